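"""Phylogenetic regression of log-richness on stem age and signal tests.

Implements generalized least squares with a Brownian-motion covariance
derived from the timetree (PGLS), its Pagel's-lambda variant, plain OLS,
maximum-likelihood estimation of Pagel's lambda for log-richness,
independent-contrasts signal tests, per-subtree regression scans and
age-truncation subsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from cladeage.clade_data import CladeDataset

__all__ = [
    "RegressionResult",
    "SignalResult",
    "ContrastsTestResult",
    "SubtreeScanResult",
    "pgls_fit",
    "estimate_lambda",
    "independent_contrasts",
    "contrasts_signal_test",
    "scan_subtrees",
    "subset_by_age",
]


@dataclass(frozen=True)
class RegressionResult:
    """Slope of log-richness per My of stem age, with its t-test."""

    slope: float
    intercept: float
    se_slope: float
    t_statistic: float
    p_value: float
    df: int
    n: int
    covariance_model: str  # "BM" | "lambda" | "identity"
    log_base: float
    sigma2: float
    lambda_value: Optional[float] = None


@dataclass(frozen=True)
class SignalResult:
    """ML Pagel's lambda for a tip trait, against the non-phylogenetic model."""

    Lambda_ml: float
    loglik: float
    loglik_lambda0: float
    delta_aic: float  # AIC(lambda=0) - AIC(ML); positive favours signal
    bm_root_state: float
    bm_variance_rate: float
    at_boundary: bool
    contrasts_p: Optional[float] = None


def _log_values(dataset: CladeDataset, log_base: float) -> np.ndarray:
    return np.log(dataset.richness_array().astype(float)) / math.log(log_base)


def _lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    Vl = lam * V
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


def _zero_length_cherries(dataset: CladeDataset, V: np.ndarray) -> list:
    names = dataset.names
    bad = []
    n = V.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if V[i, j] >= min(V[i, i], V[j, j]) - 1e-12:
                bad.append((names[i], names[j]))
    return bad


def _gls(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    """GLS estimates, residual quadratic form and log|V| via Cholesky."""
    try:
        c = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"phylogenetic covariance is singular: {exc}") from exc
    Vinv_X = linalg.cho_solve(c, X)
    Vinv_y = linalg.cho_solve(c, y)
    XtVinvX = X.T @ Vinv_X
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    resid = y - X @ beta
    rss = float(resid @ linalg.cho_solve(c, resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    return beta, rss, XtVinvX, logdet


def pgls_fit(dataset: CladeDataset, covariance_model: str = "BM",
             log_base: float = math.e, lambda_value: Optional[float] = None,
             values: Optional[np.ndarray] = None,
             predictor: Optional[np.ndarray] = None) -> RegressionResult:
    """Regress log-richness on stem age under a phylogenetic covariance.

    ``covariance_model``: "BM" (Brownian motion on the timetree), "lambda"
    (BM with off-diagonals scaled by ``lambda_value``) or "identity"
    (ordinary least squares).  ``values`` overrides the response (already on
    the log scale) and ``predictor`` the regressor (default: stem ages).
    The slope is tested with a two-tailed t-test on df = n - 2.
    """
    n = dataset.n_clades
    if n < 3:
        raise ValueError("need at least 3 clades for regression")
    x = (np.asarray(predictor, dtype=float) if predictor is not None
         else dataset.stem_age_array())
    y = (np.asarray(values, dtype=float) if values is not None
         else _log_values(dataset, log_base))
    X = np.column_stack([np.ones(n), x])

    model = covariance_model.upper() if covariance_model.lower() != "lambda" \
        else "lambda"
    if model == "IDENTITY":
        V = np.eye(n)
        model = "identity"
    else:
        V = dataset.tree.vcv(order=dataset.names)
        if model == "lambda":
            if lambda_value is None:
                raise ValueError("lambda covariance requires lambda_value")
            V = _lambda_transform(V, lambda_value)
        elif model == "BM":
            pass
        else:
            raise ValueError(f"unknown covariance model {covariance_model!r}")

    try:
        beta, rss, XtVinvX, _ = _gls(X, y, V)
    except np.linalg.LinAlgError:
        cherries = _zero_length_cherries(dataset, V) if model != "identity" \
            else []
        raise np.linalg.LinAlgError(
            "singular phylogenetic covariance"
            + (f"; zero-length cherries: {cherries[:5]}" if cherries else ""))
    df = n - 2
    sigma2 = rss / df
    cov_beta = sigma2 * np.linalg.inv(XtVinvX)
    se = math.sqrt(max(cov_beta[1, 1], 0.0))
    # a residual norm at machine-epsilon scale means the response is an
    # exact linear function of the design (e.g. constant richness)
    degenerate = rss <= 1e-20 * max(float(y @ y), 1.0)
    if se == 0.0 or degenerate:
        tstat = 0.0
        p = 1.0
    else:
        tstat = beta[1] / se
        p = 2.0 * stats.t.sf(abs(tstat), df)
    return RegressionResult(
        slope=float(beta[1]), intercept=float(beta[0]), se_slope=se,
        t_statistic=float(tstat), p_value=float(p), df=df, n=n,
        covariance_model=model, log_base=log_base, sigma2=float(sigma2),
        lambda_value=lambda_value if model == "lambda" else None)


def _profile_loglik(lam: float, V: np.ndarray, y: np.ndarray):
    """ML profile log-likelihood of the lambda model (mu, sigma2 profiled)."""
    n = y.size
    Vl = _lambda_transform(V, lam)
    X = np.ones((n, 1))
    try:
        beta, rss, _, logdet = _gls(X, y, Vl)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    sigma2 = rss / n
    if sigma2 <= 0:
        return -np.inf, float(beta[0]), 0.0
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return ll, float(beta[0]), sigma2


def estimate_lambda(dataset: CladeDataset, log_base: float = math.e,
                    values: Optional[np.ndarray] = None) -> SignalResult:
    """ML Pagel's lambda for log-richness (or a supplied trait) on the tree.

    Fits y ~ Normal(mu 1, sigma2 V_lambda) by profile likelihood over
    lambda in [0, 1] and compares by AIC against the lambda = 0
    (non-phylogenetic) model.  A boundary estimate is reported, not clipped.
    """
    if dataset.n_clades < 4:
        raise ValueError("need at least 4 clades to estimate lambda")
    y = (np.asarray(values, dtype=float) if values is not None
         else _log_values(dataset, log_base))
    V = dataset.tree.vcv(order=dataset.names)

    res = optimize.minimize_scalar(
        lambda lam: -_profile_loglik(lam, V, y)[0],
        bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-8})
    lam_ml = float(res.x)
    ll_ml, root, sigma2 = _profile_loglik(lam_ml, V, y)
    ll0, root0, sigma20 = _profile_loglik(0.0, V, y)
    ll1, root1, sigma21 = _profile_loglik(1.0, V, y)
    # endpoints are never interior to the bounded search; check explicitly
    for lam_c, ll_c, root_c, s2_c in ((0.0, ll0, root0, sigma20),
                                      (1.0, ll1, root1, sigma21)):
        if ll_c > ll_ml:
            lam_ml, ll_ml, root, sigma2 = lam_c, ll_c, root_c, s2_c
    aic_ml = -2 * ll_ml + 2 * 3   # mu, sigma2, lambda
    aic_0 = -2 * ll0 + 2 * 2      # mu, sigma2
    at_boundary = lam_ml < 1e-6 or lam_ml > 1 - 1e-6
    return SignalResult(
        Lambda_ml=lam_ml, loglik=ll_ml, loglik_lambda0=ll0,
        delta_aic=float(aic_0 - aic_ml), bm_root_state=root,
        bm_variance_rate=float(sigma2), at_boundary=at_boundary)


def independent_contrasts(dataset: CladeDataset,
                          values: Optional[np.ndarray] = None,
                          log_base: float = math.e) -> np.ndarray:
    """Standardized (Felsenstein) independent contrasts of a tip trait.

    Requires a binary tree; a zero expected variance at any contrast (two
    zero-length branches meeting) is an error — jitter the offending branch
    lengths or collapse the cherry before testing.
    """
    y = (np.asarray(values, dtype=float) if values is not None
         else _log_values(dataset, log_base))
    lookup = dict(zip(dataset.names, y))
    contrasts = []
    tree = dataset.tree.dendropy_tree
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._pic_value = lookup[node.taxon.label]
            node._pic_extra = node.edge.length or 0.0
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError("independent contrasts require a binary tree")
        a, b = children
        va, vb = a._pic_extra, b._pic_extra
        total = va + vb
        if total <= 0:
            raise ValueError(
                "zero expected variance for a contrast (two zero-length "
                "branches meet); collapse the cherry or jitter its lengths")
        contrasts.append((a._pic_value - b._pic_value) / math.sqrt(total))
        node._pic_value = (vb * a._pic_value + va * b._pic_value) / total
        node._pic_extra = (node.edge.length or 0.0) + va * vb / total
    return np.array(contrasts)


@dataclass(frozen=True)
class ContrastsTestResult:
    statistic: float  # observed variance of standardized contrasts
    p_value: float
    mode: str
    n_permutations: int
    null_mean_log: Optional[float] = None
    null_sd_log: Optional[float] = None


def contrasts_signal_test(dataset: CladeDataset, n_permutations: int = 999,
                          mode: str = "permutation",
                          values: Optional[np.ndarray] = None,
                          log_base: float = math.e,
                          seed: Optional[int] = None) -> ContrastsTestResult:
    """Signal test on the variance of standardized independent contrasts.

    Phylogenetic signal makes neighbouring tips similar, so the observed
    contrast variance falls below its distribution under random reshuffling
    of tip values.  ``mode="permutation"`` reports the one-tailed
    permutation p-value, bounded below by 1/(n_permutations + 1);
    ``mode="analytic"`` fits a normal to the permuted log-variances and
    reports the normal tail of the observed log-variance, which can resolve
    extremely small p-values.
    """
    if mode not in ("permutation", "analytic"):
        raise ValueError("mode must be 'permutation' or 'analytic'")
    y = (np.asarray(values, dtype=float) if values is not None
         else _log_values(dataset, log_base))
    rng = np.random.default_rng(seed)
    obs = float(np.var(independent_contrasts(dataset, values=y), ddof=1))
    if obs == 0.0:
        # degenerate: all contrasts zero; report the resolution floor
        return ContrastsTestResult(statistic=0.0,
                                   p_value=1.0 / (n_permutations + 1),
                                   mode=mode, n_permutations=n_permutations)
    perm_stats = np.empty(n_permutations)
    yp = y.copy()
    for k in range(n_permutations):
        rng.shuffle(yp)
        perm_stats[k] = np.var(independent_contrasts(dataset, values=yp),
                               ddof=1)
    if mode == "permutation":
        p = (1 + int(np.sum(perm_stats <= obs))) / (n_permutations + 1)
        return ContrastsTestResult(statistic=obs, p_value=float(p), mode=mode,
                                   n_permutations=n_permutations)
    logs = np.log(perm_stats[perm_stats > 0])
    m, s = float(np.mean(logs)), float(np.std(logs, ddof=1))
    if s == 0:
        raise ValueError("permutation null is degenerate")
    p = float(stats.norm.cdf((math.log(obs) - m) / s))
    return ContrastsTestResult(statistic=obs, p_value=p, mode=mode,
                               n_permutations=n_permutations,
                               null_mean_log=m, null_sd_log=s)


@dataclass
class SubtreeScanResult:
    """Per-subtree age-richness regressions across a timetree."""

    table: pd.DataFrame  # node_id, n_tips, slope, t, p, significant, bonferroni_p
    n_subtrees: int
    n_significant_positive: int
    n_significant_negative: int
    alpha: float
    min_tips: int
    excluded_tips: list


def scan_subtrees(dataset: CladeDataset, min_tips: int = 10,
                  alpha: float = 0.05,
                  exclude: Optional[Sequence[str]] = None,
                  covariance_model: str = "BM",
                  log_base: float = math.e) -> SubtreeScanResult:
    """PGLS of log-richness on stem age within every qualifying subtree.

    A subtree qualifies when it holds at least ``min_tips`` terminals of the
    reconciled dataset (the root itself included).  Significance is assessed
    at ``alpha`` with no multiple-testing correction; a Bonferroni-adjusted
    p-value column is emitted for reference only.  ``exclude`` removes named
    tips before scanning (the "trickle-down" check: dropping a dominant
    subtree's tips shows whether significance higher up was inherited).
    """
    if exclude:
        keep = [nm for nm in dataset.names if nm not in set(exclude)]
        dataset = dataset.subset(keep)
    names = dataset.names
    index = {nm: i for i, nm in enumerate(names)}
    x = dataset.stem_age_array()
    y = _log_values(dataset, log_base)
    V = (dataset.tree.vcv(order=names)
         if covariance_model.upper() != "IDENTITY" else np.eye(len(names)))

    rows = []
    node_id = -1
    tree = dataset.tree.dendropy_tree
    dataset.tree._leaf_depths()  # ensure _ca_depth is set
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._scan_tips = [index[node.taxon.label]]
            continue
        node._scan_tips = [i for c in node.child_nodes() for i in c._scan_tips]
        node_id += 1
        tips = node._scan_tips
        if len(tips) < min_tips:
            continue
        ix = np.array(sorted(tips))
        Vsub = V[np.ix_(ix, ix)].copy()
        if covariance_model.upper() != "IDENTITY":
            Vsub -= node._ca_depth  # re-root covariance at the subtree root
        Xs = np.column_stack([np.ones(ix.size), x[ix]])
        try:
            beta, rss, XtVinvX, _ = _gls(Xs, y[ix], Vsub)
        except np.linalg.LinAlgError:
            rows.append((node_id, ix.size, np.nan, np.nan, np.nan))
            continue
        df = ix.size - 2
        sigma2 = rss / df
        se = math.sqrt(max(sigma2 * np.linalg.inv(XtVinvX)[1, 1], 0.0))
        tstat = beta[1] / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(tstat), df) if se > 0 else 1.0
        rows.append((node_id, ix.size, float(beta[1]), float(tstat),
                     float(p)))
    table = pd.DataFrame(rows, columns=["node_id", "n_tips", "slope", "t",
                                        "p"])
    m = len(table)
    table["significant"] = table["p"] < alpha
    table["bonferroni_p"] = np.minimum(table["p"] * max(m, 1), 1.0)
    pos = int(((table["p"] < alpha) & (table["slope"] > 0)).sum())
    neg = int(((table["p"] < alpha) & (table["slope"] < 0)).sum())
    return SubtreeScanResult(
        table=table, n_subtrees=m, n_significant_positive=pos,
        n_significant_negative=neg, alpha=alpha, min_tips=min_tips,
        excluded_tips=list(exclude) if exclude else [])


def subset_by_age(dataset: CladeDataset, max_age: float) -> CladeDataset:
    """Restrict the dataset to clades with stem age strictly below ``max_age``."""
    if max_age <= 0:
        raise ValueError("max_age must be positive")
    ages = dataset.stem_age_array()
    keep = [nm for nm, a in zip(dataset.names, ages) if a < max_age]
    if not keep:
        raise ValueError(f"no clades younger than {max_age} My")
    if len(keep) == dataset.n_clades:
        return dataset
    if len(keep) < 3:
        raise ValueError(
            f"only {len(keep)} clades younger than {max_age} My; "
            "too few for analysis")
    return dataset.subset(keep)
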