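"""Synthetic timetrees and clade-richness datasets.

Generates data with the statistical structure the analyses assume —
ultrametric backbone trees (tens to ~1,500 tips, stem ages of a few to a few
hundred My) and per-clade species richness with strong right skew — together
with a ground-truth record sufficient to replay every draw.  Four richness
models are available:

``constant_rate``
    every clade diversifies under one birth-death rate pair; richness is a
    survival-conditioned progeny draw at the clade's stem age (age and
    richness are strongly coupled),
``lognormal_relaxed``
    clade net rates are drawn i.i.d. from LogNormal(m, s) at a fixed
    relative extinction, then richness as above (coupling is diluted by the
    rate spread),
``bm_signal_only``
    log-richness evolves by Brownian motion on the (lambda-transformed)
    tree: heritable clade size but, by construction, no dependence on age,
``higher_taxon_process``
    the two-state lineage/higher-taxon simulator (see
    :mod:`cladeage.higher_taxon_sim`).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
from dendropy.model import birthdeath as _bd

from cladeage.birthdeath_core import BDParams, sample_progeny
from cladeage.clade_data import CladeDataset, CladeRecord, TimeTree

__all__ = ["GeneratorSpec", "generate_timetree", "generate_clade_dataset",
           "PRESETS"]

# named parameter presets for commonly exercised regimes; convenience
# defaults, not claims about any particular empirical dataset
PRESETS = {
    # heritable clade size, no age effect; signal level typical of
    # log-richness on large timetrees
    "signal_only": {"richness_model": "bm_signal_only",
                    "Lambda": 0.724, "bm_root": math.log(50.0),
                    "bm_rate": 0.02},
    # single moderate-turnover regime, ages predict richness
    "constant_rate": {"richness_model": "constant_rate",
                      "lam": 0.1, "mu": 0.05},
    # plant-radiation-like high turnover (r = 0.07, eps ~ 0.9)
    "high_turnover": {"richness_model": "constant_rate",
                      "lam": 0.71, "mu": 0.64},
    # strongly heterogeneous rates across clades
    "lognormal_relaxed": {"richness_model": "lognormal_relaxed",
                          "m": math.log(0.1), "s": 0.5, "epsilon": 0.0},
}


def generate_timetree(n_tips: int, backbone: str = "yule", lam: float = 0.03,
                      mu: float = 0.0, seed: Optional[int] = None,
                      crown_age: Optional[float] = None,
                      rng: Optional[np.random.Generator] = None,
                      n_deep_clades: int = 10,
                      radiation_lam: float = 0.1) -> TimeTree:
    """Simulate a reconstructed ultrametric tree with exactly ``n_tips`` tips.

    Backbones: "yule" (pure birth), "birth_death", or "two_level" — a deep
    Yule backbone of ``n_deep_clades`` old lineages, each carrying a much
    younger nested radiation, the structure typical of assembled
    higher-taxon supertrees (a few ancient splits, many recent ones).  The
    single-level processes run until the target number of extant lineages
    is reached and all terminals are then extended by a common exponential
    hold time (memorylessness makes this a valid stopping rule and
    guarantees strictly positive pendant branches).  ``crown_age``
    optionally rescales the tree to a fixed root height in My (default
    400 My for the two-level backbone).
    """
    if n_tips < 4:
        raise ValueError("n_tips must be >= 4")
    if rng is None:
        rng = np.random.default_rng(seed)
    if backbone == "two_level":
        return _two_level_tree(n_tips, rng, lam,
                               crown_age if crown_age is not None else 400.0,
                               n_deep_clades, radiation_lam)
    if backbone == "yule":
        mu = 0.0
    elif backbone != "birth_death":
        raise ValueError(
            "backbone must be 'yule', 'birth_death' or 'two_level'")
    pyrng = random.Random(int(rng.integers(2 ** 31)))
    tree = _bd.birth_death_tree(
        birth_rate=lam, death_rate=mu, num_extant_tips=n_tips,
        rng=pyrng, repeat_until_success=True)
    hold = rng.exponential(1.0 / (n_tips * (lam + mu)))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + hold
    tt = TimeTree(tree, validate=False)
    if crown_age is not None:
        scale = crown_age / tt.root_height
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
        tt = TimeTree(tree, validate=False)
    # relabel tips deterministically
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"clade{i + 1:04d}"
    return tt


def _two_level_tree(n_tips: int, rng: np.random.Generator, lam: float,
                    crown_age: float, n_deep_clades: int,
                    radiation_lam: float) -> TimeTree:
    """Deep backbone of old lineages, each tipped by a young radiation."""
    if n_tips < 4 * n_deep_clades:
        raise ValueError("two-level backbone needs n_tips >= 4 * "
                         f"n_deep_clades ({4 * n_deep_clades})")
    backbone = generate_timetree(n_deep_clades, backbone="yule", lam=lam,
                                 rng=rng, crown_age=crown_age)
    bt = backbone.dendropy_tree
    counts = 4 + rng.multinomial(n_tips - 4 * n_deep_clades,
                                 np.ones(n_deep_clades) / n_deep_clades)
    for k, leaf in enumerate(list(bt.leaf_node_iter())):
        pend = leaf.edge.length
        sub = generate_timetree(int(counts[k]), backbone="yule",
                                lam=radiation_lam, rng=rng)
        # the radiation's crown sits a random fraction down the old pendant
        crown = float(rng.uniform(0.3, 0.9)) * pend
        st = sub.dendropy_tree
        scale = crown / sub.root_height
        for e in st.preorder_edge_iter():
            if e.length is not None:
                e.length *= scale
        leaf.edge.length = pend - crown
        for child in st.seed_node.child_nodes():
            leaf.add_child(child)
        leaf.taxon = None
    ns = dendropy.TaxonNamespace()
    bt.taxon_namespace = ns
    for i, lf in enumerate(bt.leaf_node_iter()):
        lf.taxon = ns.new_taxon(f"clade{i + 1:04d}")
    return TimeTree(bt, validate=False)


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic clade dataset.

    Exactly one richness model applies; model-specific fields are read from
    the matching attributes.  ``preset`` fills fields from :data:`PRESETS`.
    """

    n_tips: int = 200
    backbone: str = "yule"
    backbone_lam: float = 0.03
    backbone_mu: float = 0.0
    crown_age: Optional[float] = None
    n_deep_clades: int = 10      # two_level backbone only
    radiation_lam: float = 0.1   # two_level backbone only
    richness_model: str = "constant_rate"
    # constant_rate / high turnover
    lam: float = 0.1
    mu: float = 0.05
    # lognormal_relaxed
    m: float = math.log(0.1)
    s: float = 0.5
    epsilon: float = 0.0
    # bm_signal_only
    Lambda: float = 0.724
    bm_root: float = math.log(50.0)
    bm_rate: float = 0.02
    # higher_taxon_process
    sim_config: Optional[object] = None
    seed: Optional[int] = None

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "GeneratorSpec":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; "
                           f"available: {sorted(PRESETS)}")
        kw = dict(PRESETS[name])
        kw.update(overrides)
        return cls(**kw)


def _bm_on_tree(dataset_tree: TimeTree, order: list, Lambda: float,
                root: float, rate: float, rng: np.random.Generator,
                size: int = 1) -> np.ndarray:
    V = dataset_tree.vcv(order=order)
    Vl = Lambda * V
    np.fill_diagonal(Vl, np.diag(V))
    L = np.linalg.cholesky(rate * Vl + 1e-12 * np.eye(V.shape[0]))
    z = rng.standard_normal((size, V.shape[0]))
    return root + z @ L.T


def generate_clade_dataset(spec: GeneratorSpec
                           ) -> tuple[CladeDataset, dict]:
    """Generate a (tree, richness) dataset plus its ground-truth record.

    The truth dictionary contains everything needed to replay the dataset:
    the seed, the model name and parameters, and per-clade latent values
    (net rates, unrounded Brownian log-richness, taxon formation times)
    where the model has them.
    """
    rng = np.random.default_rng(spec.seed)
    truth: dict = {"seed": spec.seed, "richness_model": spec.richness_model}

    if spec.richness_model == "higher_taxon_process":
        from cladeage.higher_taxon_sim import simulate_higher_taxon_tree
        if spec.sim_config is None:
            raise ValueError("higher_taxon_process requires sim_config")
        sim = None
        for attempt in range(10_000):
            sim = simulate_higher_taxon_tree(spec.sim_config, rng)
            if sim is not None:
                break
        if sim is None:
            raise RuntimeError("higher-taxon simulation rejected 10,000 times")
        records = [CladeRecord(name=nm, richness=ri)
                   for nm, ri in zip(sim.tree.tip_labels, sim.richness)]
        truth.update({"states": list(sim.states),
                      "formation_times": list(sim.formation_times),
                      "attempts": attempt + 1})
        return CladeDataset(tree=sim.tree, records=records), truth

    tree = generate_timetree(spec.n_tips, backbone=spec.backbone,
                             lam=spec.backbone_lam, mu=spec.backbone_mu,
                             crown_age=spec.crown_age, rng=rng,
                             n_deep_clades=spec.n_deep_clades,
                             radiation_lam=spec.radiation_lam)
    names = tree.tip_labels
    ages = tree.stem_ages()
    age_vec = np.array([ages[nm] for nm in names])

    if spec.richness_model == "constant_rate":
        params = BDParams(spec.lam, spec.mu)
        richness = np.array([
            sample_progeny(params, t, conditioned=True, rng=rng)
            for t in age_vec], dtype=np.int64)
        truth.update({"lam": spec.lam, "mu": spec.mu})
    elif spec.richness_model == "lognormal_relaxed":
        rates = rng.lognormal(mean=spec.m, sigma=spec.s, size=len(names))
        richness = np.empty(len(names), dtype=np.int64)
        for i, (r_i, t) in enumerate(zip(rates, age_vec)):
            p = BDParams.from_r_epsilon(r_i, spec.epsilon)
            richness[i] = sample_progeny(p, t, conditioned=True, rng=rng)
        truth.update({"m": spec.m, "s": spec.s, "epsilon": spec.epsilon,
                      "rates": rates.tolist()})
    elif spec.richness_model == "bm_signal_only":
        logvals = _bm_on_tree(tree, names, spec.Lambda, spec.bm_root,
                              spec.bm_rate, rng)[0]
        richness = np.maximum(1, np.rint(np.exp(logvals))).astype(np.int64)
        truth.update({"Lambda": spec.Lambda, "bm_root": spec.bm_root,
                      "bm_rate": spec.bm_rate,
                      "log_values": logvals.tolist()})
    else:
        raise ValueError(f"unknown richness model {spec.richness_model!r}")

    records = [CladeRecord(name=nm, richness=int(ri))
               for nm, ri in zip(names, richness)]
    truth["richness"] = richness.tolist()
    return CladeDataset(tree=tree, records=records), truth
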