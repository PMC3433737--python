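"""Orchestration of the full age-richness analysis.

Stage order: data reconciliation -> PGLS + signal tests -> stepwise
rate-shift fit -> higher-taxon simulator null -> relaxed-rate posterior
predictive SES -> robustness studies.  Each stage writes TSV/JSON outputs
into the run directory; a summary JSON collects the headline numbers.
Stages are cached by a hash of the configuration: re-running with an
unchanged config and seed skips completed stages, and all floating-point
output is formatted at 12 significant digits so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from cladeage import clade_data
from cladeage.birthdeath_core import fit_constant_rate_ml
from cladeage.clade_data import CladeDataset
from cladeage import comparative_regression as creg
from cladeage import higher_taxon_sim as hts
from cladeage import medusa_fit
from cladeage import relaxed_rate_bayes as rrb
from cladeage import robustness_sims as rob

log = logging.getLogger("cladeage")

__all__ = ["RunConfig", "run_pipeline"]

FLOAT_FMT = "%.12g"


def _fmt(x) -> str:
    if isinstance(x, float):
        return FLOAT_FMT % x
    return str(x)


def write_tsv(path: Path, header: Sequence[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, frozenset):
            return sorted(o)
        raise TypeError(f"not serializable: {type(o)}")
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=default) + "\n")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    tree_path: str
    richness_path: str
    output_dir: str
    seed: int = 0
    log_base: float = math.e
    covariance_model: str = "BM"
    scan_min_tips: int = 10
    scan_alpha: float = 0.05
    truncation_ages: Sequence[float] = (50.0, 100.0, 150.0, 200.0, 250.0)
    contrast_permutations: int = 999
    medusa_max_shifts: Optional[int] = None
    medusa_include_backbone: bool = True
    null_n_accepted: int = 1000
    mcmc_iterations: int = 20_000
    mcmc_chains: int = 2
    ppc_draws: int = 500
    epsilons: Sequence[float] = (0.0, 0.99)
    signal_n_datasets: int = 500
    age_error_n_sims: int = 1000
    age_error_deltas: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(canon.encode()).hexdigest()[:12]


def _child_seed(config: RunConfig, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the global seed."""
    h = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


class _StageRunner:
    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.hash = config.config_hash()

    def cached(self, stage: str) -> Optional[dict]:
        marker = self.outdir / f"{stage}.done.json"
        if marker.exists():
            data = json.loads(marker.read_text())
            if data.get("config_hash") == self.hash:
                log.info("stage %s: cached (hash %s)", stage, self.hash)
                return data["summary"]
        return None

    def done(self, stage: str, summary: dict, t0: float) -> dict:
        marker = self.outdir / f"{stage}.done.json"
        write_json(marker, {"config_hash": self.hash, "summary": summary,
                            "seed": _child_seed(self.config, stage)})
        log.info("stage %s: finished in %.1fs", stage, time.time() - t0)
        return summary


def _stage_data(runner: _StageRunner) -> tuple[CladeDataset, dict]:
    cfg = runner.config
    tree = clade_data.read_timetree(cfg.tree_path)
    records = clade_data.load_richness(cfg.richness_path)
    dataset, report = clade_data.reconcile(tree, records)
    summary = clade_data.summarize(dataset)
    (runner.outdir / "reconciliation_report.json").write_text(
        report.to_json() + "\n")
    frame = dataset.to_frame()
    write_tsv(runner.outdir / "reconciled_dataset.tsv",
              ["name", "stem_age", "richness"],
              frame.itertuples(index=False))
    return dataset, summary


def _stage_regression(runner: _StageRunner, dataset: CladeDataset) -> dict:
    cfg = runner.config
    fit = creg.pgls_fit(dataset, covariance_model=cfg.covariance_model,
                        log_base=cfg.log_base)
    ols = creg.pgls_fit(dataset, covariance_model="identity",
                        log_base=cfg.log_base)
    sig = creg.estimate_lambda(dataset, log_base=cfg.log_base)
    ct = creg.contrasts_signal_test(
        dataset, n_permutations=cfg.contrast_permutations, mode="analytic",
        log_base=cfg.log_base, seed=_child_seed(cfg, "contrasts"))
    scan = creg.scan_subtrees(dataset, min_tips=cfg.scan_min_tips,
                              alpha=cfg.scan_alpha,
                              covariance_model=cfg.covariance_model,
                              log_base=cfg.log_base)
    scan.table.to_csv(runner.outdir / "subtree_scan.tsv", sep="\t",
                      index=False, float_format=FLOAT_FMT)
    rows = []
    for max_age in cfg.truncation_ages:
        try:
            sub = creg.subset_by_age(dataset, max_age)
            f = creg.pgls_fit(sub, covariance_model=cfg.covariance_model,
                              log_base=cfg.log_base)
            rows.append((max_age, sub.n_clades, f.slope, f.t_statistic,
                         f.p_value, f.df))
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("truncation %s skipped: %s", max_age, exc)
    write_tsv(runner.outdir / "truncation_fits.tsv",
              ["max_age", "n", "slope", "t", "p", "df"], rows)
    summary = {
        "pgls": {"slope": fit.slope, "t": fit.t_statistic, "p": fit.p_value,
                 "df": fit.df},
        "ols": {"slope": ols.slope, "t": ols.t_statistic, "p": ols.p_value},
        "lambda_ml": sig.Lambda_ml, "delta_aic": sig.delta_aic,
        "contrasts_p": ct.p_value,
        "scan": {"n_subtrees": scan.n_subtrees,
                 "significant_positive": scan.n_significant_positive,
                 "significant_negative": scan.n_significant_negative},
    }
    write_json(runner.outdir / "regression_summary.json", summary)
    return summary


def _stage_medusa(runner: _StageRunner, dataset: CladeDataset
                  ) -> tuple[medusa_fit.MedusaResult, dict]:
    cfg = runner.config
    res = medusa_fit.stepwise_fit(
        dataset, max_shifts=cfg.medusa_max_shifts,
        include_backbone=cfg.medusa_include_backbone)
    write_json(runner.outdir / "medusa_fit.json", res.to_dict())
    write_tsv(runner.outdir / "medusa_table.tsv",
              ["Clades", "N", "AICc-1", "AICc-MEDUSA", "Shifts", "np"],
              [(dataset.n_clades, int(dataset.richness_array().sum()),
                res.aicc_single, res.aicc_best, res.n_shifts, res.np)])
    summary = {"n_shifts": res.n_shifts, "np": res.np,
               "aicc_single": res.aicc_single, "aicc_best": res.aicc_best}
    return res, summary


def _stage_null(runner: _StageRunner, dataset: CladeDataset,
                medusa: medusa_fit.MedusaResult) -> dict:
    cfg = runner.config
    sim_cfg = hts.SimConfig.from_medusa(
        medusa, dataset.tree, observed_n_terminals=dataset.n_clades,
        n_accepted_target=cfg.null_n_accepted)
    null = hts.build_null(sim_cfg, dataset, seed=_child_seed(cfg, "null"))
    write_tsv(runner.outdir / "null_rho.tsv", ["rho"],
              [(float(r),) for r in null.rho])
    summary = null.summary()
    write_json(runner.outdir / "null_summary.json", summary)
    return summary


def _stage_relaxed(runner: _StageRunner, dataset: CladeDataset) -> dict:
    cfg = runner.config
    beta_obs = creg.pgls_fit(dataset, covariance_model=cfg.covariance_model,
                             log_base=cfg.log_base)
    out = {"beta": beta_obs.slope, "p": beta_obs.p_value}
    for eps in cfg.epsilons:
        post = rrb.run_mcmc(
            dataset, epsilon=eps,
            settings=rrb.McmcSettings(n_iterations=cfg.mcmc_iterations,
                                      n_chains=cfg.mcmc_chains,
                                      seed=_child_seed(cfg, f"mcmc{eps}")))
        write_tsv(runner.outdir / f"chain_eps{eps}.tsv",
                  ["m", "s", "log_posterior"],
                  zip(post.m, post.s, post.log_posterior))
        rng = np.random.default_rng(_child_seed(cfg, f"ppc{eps}"))
        sims = rrb.posterior_predictive(dataset, post, cfg.ppc_draws, rng)
        ses = rrb.standardized_effect_size(
            dataset, sims, covariance_model=cfg.covariance_model,
            log_base=cfg.log_base, beta_obs=beta_obs.slope)
        out[f"ses_eps{eps}"] = ses.ses
        out[f"tail_probability_eps{eps}"] = ses.tail_probability
        out[f"diagnostics_eps{eps}"] = post.diagnostics
    write_json(runner.outdir / "ses_report.json", out)
    return out


def _stage_robustness(runner: _StageRunner, dataset: CladeDataset) -> dict:
    cfg = runner.config
    sig_cfg = rob.SignalSimConfig.from_fitted_signal(
        dataset, n_datasets=cfg.signal_n_datasets,
        seed=_child_seed(cfg, "signal"))
    t1 = rob.type1_error_study(sig_cfg, alpha=cfg.scan_alpha)
    t1.p_histogram().to_csv(runner.outdir / "type1_p_histogram.tsv",
                            sep="\t", index=False)
    bd_fit = fit_constant_rate_ml(dataset)
    ae_cfg = rob.AgeErrorConfig(
        ages=dataset.stem_age_array(), bd=bd_fit.params,
        delta_grid=cfg.age_error_deltas, n_sims=cfg.age_error_n_sims,
        seed=_child_seed(cfg, "age_error"))
    table, _ = rob.age_error_study(ae_cfg, statistic="both")
    table.to_csv(runner.outdir / "age_error_summary.tsv", sep="\t",
                 index=False, float_format=FLOAT_FMT)
    summary = {
        "ols_type1": t1.ols_rejection_rate,
        "pgls_type1": t1.pgls_rejection_rate,
        "bd_lambda": bd_fit.params.lam, "bd_mu": bd_fit.params.mu,
        "age_error": table.to_dict(orient="records"),
    }
    write_json(runner.outdir / "robustness_summary.json", summary)
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the merged summary (also written to disk)."""
    runner = _StageRunner(config)
    config.to_yaml(runner.outdir / "config.yaml")
    summary: dict = {"seed": config.seed, "config_hash": runner.hash}

    t0 = time.time()
    dataset, data_summary = _stage_data(runner)
    summary["data"] = runner.cached("data") or runner.done(
        "data", data_summary, t0)

    for stage, fn in (("regression", _stage_regression),):
        cached = runner.cached(stage)
        if cached is None:
            t0 = time.time()
            cached = runner.done(stage, fn(runner, dataset), t0)
        summary[stage] = cached

    cached = runner.cached("medusa")
    medusa_res = None
    if cached is None:
        t0 = time.time()
        medusa_res, medusa_summary = _stage_medusa(runner, dataset)
        cached = runner.done("medusa", medusa_summary, t0)
    summary["medusa"] = cached

    cached = runner.cached("null")
    if cached is None:
        if medusa_res is None:
            medusa_res, _ = _stage_medusa(runner, dataset)
        t0 = time.time()
        cached = runner.done("null", _stage_null(runner, dataset,
                                                 medusa_res), t0)
    summary["null"] = cached

    for stage, fn in (("relaxed", _stage_relaxed),
                      ("robustness", _stage_robustness)):
        cached = runner.cached(stage)
        if cached is None:
            t0 = time.time()
            cached = runner.done(stage, fn(runner, dataset), t0)
        summary[stage] = cached

    write_json(runner.outdir / "summary.json", summary)
    return summary
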