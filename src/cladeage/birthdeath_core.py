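"""Closed-form constant-rate birth-death mathematics.

A single lineage alive at time 0 speciates at rate ``lambda`` and goes
extinct at rate ``mu`` (both per lineage per million years).  After an
elapsed time ``t`` the number of extant descendants ``N(t)`` follows the
classical Kendall geometric-tail law

    P(N = 0)      = a_t
    P(N = n >= 1) = (1 - a_t) (1 - b_t) b_t^(n-1)

with, writing ``r = lambda - mu`` for the net diversification rate,

    a_t = mu (e^{rt} - 1) / (lambda e^{rt} - mu)
    b_t = lambda (e^{rt} - 1) / (lambda e^{rt} - mu)

and the balanced limit ``a_t = b_t = lambda t / (1 + lambda t)`` when
``mu = lambda``.  "Conditioned" throughout means conditioned on clade
survival (at least one extant descendant at time t); the conditioned
expectation of the balanced process is the linear law ``N(t) = 1 + lambda t``.

Rates with ``mu > lambda`` (declining diversity, r < 0) are fully supported.
All probability-mass computations are carried out in log space so that
richness values up to ~1e7 do not underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

__all__ = [
    "BDParams",
    "ProgenyDistribution",
    "ConstantRateFit",
    "survival_probability",
    "expected_richness",
    "progeny_pmf",
    "progeny_logpmf",
    "sample_progeny",
    "fit_constant_rate_ml",
]

# below |r|*t = _BALANCED_SWITCH the naive a_t/b_t expressions lose precision
# to cancellation; the balanced-process forms are used instead
_BALANCED_SWITCH = 1e-8


@dataclass(frozen=True)
class BDParams:
    """A speciation/extinction rate pair (per lineage per My).

    ``mu > lam`` is explicitly permitted (negative net diversification).
    """

    lam: float
    mu: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lam) and math.isfinite(self.mu)):
            raise ValueError("rates must be finite")
        if self.lam < 0 or self.mu < 0:
            raise ValueError("rates must be non-negative")

    @property
    def r(self) -> float:
        """Net diversification rate lambda - mu (may be negative)."""
        return self.lam - self.mu

    @property
    def epsilon(self) -> float:
        """Relative extinction mu/lambda; NaN for a pure-death process."""
        if self.lam == 0:
            return math.nan
        return self.mu / self.lam

    def to_dict(self) -> dict:
        return {"lambda": self.lam, "mu": self.mu, "r": self.r,
                "epsilon": None if self.lam == 0 else self.epsilon}

    @staticmethod
    def from_r_epsilon(r: float, epsilon: float) -> "BDParams":
        """Build from net rate and relative extinction (lam = r/(1-eps))."""
        if epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if epsilon == 1.0:
            raise ValueError("epsilon = 1 does not determine lambda from r; "
                             "construct BDParams(lam, lam) directly")
        lam = r / (1.0 - epsilon)
        if lam < 0:
            raise ValueError(
                f"r={r}, epsilon={epsilon} imply a negative speciation rate")
        return BDParams(lam, epsilon * lam)


def _log_geom_terms(params: BDParams, t: float) -> tuple[float, float, float]:
    """Return (log(1 - a_t), log(b_t), log(1 - b_t)) stably.

    Uses the identity 1 - b_t = (1 - a_t) e^{-rt} and evaluates with e^{-rt}
    for r > 0 and e^{rt} for r < 0 so no exponential overflows.
    """
    lam, mu = params.lam, params.mu
    r = lam - mu
    if t < 0:
        raise ValueError("elapsed time must be non-negative")
    if t == 0.0 or (lam == 0.0 and mu == 0.0):
        return 0.0, -math.inf, 0.0
    if abs(r) * t < _BALANCED_SWITCH and lam > 0:
        # balanced limit: a = b = lam t / (1 + lam t)
        log1m = -math.log1p(lam * t)
        logb = math.log(lam * t) + log1m
        return log1m, logb, log1m
    if r > 0:
        # 1 - a = r / (lam - mu e^{-rt})
        emrt = math.exp(-r * t)
        denom = lam - mu * emrt
        log1m_a = math.log(r) - math.log(denom)
        log1m_b = log1m_a - r * t
    else:
        # r < 0:  1 - a = (-r) e^{rt} / (mu - lam e^{rt})
        ert = math.exp(r * t)
        denom = mu - lam * ert
        log1m_a = math.log(-r) + r * t - math.log(denom)
        log1m_b = log1m_a - r * t
    # b = 1 - (1 - b); log1m_b may be ~0 for tiny b
    one_m_b = math.exp(log1m_b)
    if one_m_b >= 1.0:
        logb = -math.inf
    else:
        logb = math.log1p(-one_m_b)
    return log1m_a, logb, log1m_b


def _log_geom_terms_vec(lam: float, mu: float, t: np.ndarray):
    """Vectorised (log(1-a_t), log(b_t), log(1-b_t)) over an array of times.

    Same algebra as :func:`_log_geom_terms`; used by likelihood code that
    evaluates many branches/clades under one rate pair.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("elapsed times must be non-negative")
    r = lam - mu
    log1m_a = np.zeros_like(t)
    log1m_b = np.zeros_like(t)
    logb = np.full_like(t, -np.inf)
    if lam == 0.0 and mu == 0.0:
        return log1m_a, logb, log1m_b
    active = t > 0
    ta = t[active]
    if lam > 0 and abs(r) * np.max(t, initial=0.0) < _BALANCED_SWITCH:
        l1m = -np.log1p(lam * ta)
        log1m_a[active] = l1m
        log1m_b[active] = l1m
        with np.errstate(divide="ignore"):
            logb[active] = np.log(lam * ta) + l1m
        return log1m_a, logb, log1m_b
    if r > 0:
        emrt = np.exp(-r * ta)
        l1m_a = math.log(r) - np.log(lam - mu * emrt)
    elif r < 0:
        ert = np.exp(r * ta)
        l1m_a = math.log(-r) + r * ta - np.log(mu - lam * ert)
    else:  # r == 0 exactly, lam = mu > 0
        l1m_a = -np.log1p(lam * ta)
    l1m_b = l1m_a - r * ta
    one_m_b = np.exp(l1m_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        lb = np.where(one_m_b < 1.0, np.log1p(-np.minimum(one_m_b, 1.0)),
                      -np.inf)
    log1m_a[active] = l1m_a
    log1m_b[active] = l1m_b
    logb[active] = lb
    return log1m_a, logb, log1m_b


def conditioned_logpmf_terms(lam: float, mu: float, n: np.ndarray,
                             t: np.ndarray) -> np.ndarray:
    """Per-clade log P(N = n_i | survival) under one rate pair (vectorised)."""
    n = np.asarray(n)
    _, logb, log1m_b = _log_geom_terms_vec(lam, mu, t)
    with np.errstate(invalid="ignore"):
        out = np.where(n == 1, log1m_b, log1m_b + (n - 1) * logb)
    return out


def survival_probability(params: BDParams, t: float) -> float:
    """P(at least one extant descendant after time t) for one ancestor.

    Equals ``1/(1 + lambda t)`` when mu = lambda, 1 for a pure-birth
    process, and is continuous in r across r = 0.
    """
    log1m_a, _, _ = _log_geom_terms(params, float(t))
    return math.exp(log1m_a)


def expected_richness(params: BDParams, t: float, conditioned: bool = False,
                      n0: int = 1) -> float:
    """Expected number of extant descendants after time t.

    Unconditioned: ``n0 * exp(r t)``.  Conditioned on survival (n0 = 1):
    ``exp(r t) / P(survival)``, which reduces to ``1 + lambda t`` for the
    balanced process mu = lambda.
    """
    t = float(t)
    if t < 0:
        raise ValueError("elapsed time must be non-negative")
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if not conditioned:
        return n0 * math.exp(params.r * t)
    if n0 != 1:
        raise ValueError("the conditioned expectation is defined for n0 = 1")
    _, _, log1m_b = _log_geom_terms(params, t)
    # E[N | N >= 1] = 1 / (1 - b_t)
    if log1m_b == -math.inf:
        raise ValueError("survival probability is 0; conditioned "
                         "expectation undefined")
    return math.exp(-log1m_b)


def progeny_logpmf(params: BDParams, t: float, n, conditioned: bool = False):
    """log P(N(t) = n) for the progeny-count distribution (vectorised in n).

    With ``conditioned=True`` the mass is renormalised over n >= 1
    (survival conditioning); n = 0 is then a domain error.
    """
    n = np.asarray(n)
    if np.any(n < 0):
        raise ValueError("progeny counts must be non-negative")
    if conditioned and np.any(n == 0):
        raise ValueError("n = 0 has no mass under survival conditioning")
    log1m_a, logb, log1m_b = _log_geom_terms(params, float(t))
    out = np.full(n.shape, -np.inf, dtype=float)
    pos = n >= 1
    if logb == -math.inf:
        out[pos & (n == 1)] = log1m_b if not conditioned else 0.0
        if not conditioned:
            out[pos & (n == 1)] += log1m_a
    else:
        out[pos] = log1m_b + (n[pos] - 1) * logb
        if not conditioned:
            out[pos] += log1m_a
    if not conditioned:
        # log a_t = log(1 - (1 - a_t)); a_t = 0 for pure birth or t = 0
        one_m_a = math.exp(log1m_a)
        log_a = math.log1p(-one_m_a) if one_m_a < 1.0 else -math.inf
        out = np.where(n == 0, log_a, out)
    if out.ndim == 0:
        return float(out)
    return out


def progeny_pmf(params: BDParams, t: float, n, conditioned: bool = False):
    """P(N(t) = n); see :func:`progeny_logpmf`."""
    return np.exp(progeny_logpmf(params, t, n, conditioned=conditioned))


@dataclass(frozen=True)
class ProgenyDistribution:
    """Progeny-count distribution of one lineage after ``elapsed`` My."""

    params: BDParams
    elapsed: float
    conditioned: bool = False
    _terms: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_terms",
                           _log_geom_terms(self.params, float(self.elapsed)))

    @property
    def p_extinct(self) -> float:
        """P(N = 0) (zero when conditioned)."""
        if self.conditioned:
            return 0.0
        one_m_a = math.exp(self._terms[0])
        return max(0.0, 1.0 - one_m_a)

    def logpmf(self, n):
        return progeny_logpmf(self.params, self.elapsed, n,
                              conditioned=self.conditioned)

    def pmf(self, n):
        return np.exp(self.logpmf(n))

    def mean(self) -> float:
        return expected_richness(self.params, self.elapsed,
                                 conditioned=self.conditioned, n0=1)

    def sample(self, rng: np.random.Generator, size=None):
        return sample_progeny(self.params, self.elapsed,
                              conditioned=self.conditioned, rng=rng, size=size)


def sample_progeny(params: BDParams, t: float, conditioned: bool,
                   rng: np.random.Generator, size=None):
    """Draw progeny counts exactly via the geometric structure.

    Conditioned draws are 1 + Geometric(1 - b_t); unconditioned draws are 0
    with probability a_t, else a conditioned draw.  O(1) per variate.
    """
    log1m_a, logb, log1m_b = _log_geom_terms(params, float(t))
    scalar = size is None
    shape = () if scalar else size
    if logb == -math.inf:
        draws = np.ones(shape, dtype=np.int64)
    else:
        # inverse CDF of Geometric on {1, 2, ...} with success prob 1 - b
        u = rng.random(shape)
        with np.errstate(over="ignore"):
            ratio = np.log1p(-u) / logb
        # cap astronomically large draws inside the int64 range
        draws = 1 + np.floor(np.minimum(ratio, 2.0 ** 62)).astype(np.int64)
        draws = np.maximum(draws, 1)
    if not conditioned:
        one_m_a = math.exp(log1m_a)
        dead = rng.random(shape) >= one_m_a
        draws = np.where(dead, 0, draws)
    if scalar:
        return int(draws)
    return draws


@dataclass(frozen=True)
class ConstantRateFit:
    """Result of the constant-rate ML fit."""

    params: BDParams
    loglik: float
    converged: bool
    at_boundary: bool
    message: str = ""


def _as_richness_ages(data) -> tuple[np.ndarray, np.ndarray]:
    """Accept a CladeDataset-like object or an (richness, ages) pair."""
    if hasattr(data, "richness_array"):
        return (np.asarray(data.richness_array(), dtype=float),
                np.asarray(data.stem_age_array(), dtype=float))
    n, t = data
    return np.asarray(n, dtype=float), np.asarray(t, dtype=float)


def _neg_loglik_arrays(log_lam: float, log_mu, n: np.ndarray,
                       t: np.ndarray) -> float:
    if not math.isfinite(log_lam) or log_lam > 60:
        return np.inf
    lam = math.exp(log_lam)
    mu = math.exp(log_mu) if log_mu is not None else 0.0
    if not math.isfinite(mu):
        return np.inf
    total = float(np.sum(conditioned_logpmf_terms(lam, mu, n, t)))
    if not math.isfinite(total):
        return np.inf
    return -total


def constant_rate_loglik(params: BDParams, richness, ages) -> float:
    """Sum of survival-conditioned progeny log-probabilities (vectorised)."""
    n = np.asarray(richness, dtype=np.int64)
    t = np.asarray(ages, dtype=float)
    return float(np.sum(conditioned_logpmf_terms(params.lam, params.mu, n, t)))


_LOG_RATE_LO, _LOG_RATE_HI = -14.0, 8.0


def fit_constant_rate_ml(data, epsilon: Optional[float] = None) -> ConstantRateFit:
    """Maximum-likelihood constant-rate fit to (richness, stem age) pairs.

    Maximises the sum of survival-conditioned progeny log-probabilities.
    With ``epsilon`` fixed the problem is one-dimensional in the speciation
    rate; otherwise (lambda, mu) are optimised jointly on the log scale so
    that mu > lambda is reachable.  A fit driven to the rate floor (e.g.
    all richness equal to 1, which carries no growth signal) is flagged
    ``at_boundary``.
    """
    n, t = _as_richness_ages(data)
    if n.size < 1:
        raise ValueError("need at least one clade")
    if np.any(n < 1) or np.any(t <= 0):
        raise ValueError("richness must be >= 1 and stem ages positive")

    if epsilon is not None:
        if epsilon < 0:
            raise ValueError("epsilon must be >= 0")

        def nll(log_lam: float) -> float:
            lam = math.exp(log_lam)
            return _neg_loglik_arrays(log_lam, math.log(epsilon * lam)
                                      if epsilon > 0 else None, n, t)

        res = optimize.minimize_scalar(nll, bounds=(_LOG_RATE_LO, _LOG_RATE_HI),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        lam = math.exp(res.x)
        params = BDParams(lam, epsilon * lam)
        boundary = res.x < _LOG_RATE_LO + 0.5 or res.x > _LOG_RATE_HI - 0.5
        return ConstantRateFit(params=params, loglik=-res.fun,
                               converged=bool(res.success),
                               at_boundary=boundary,
                               message=getattr(res, "message", ""))

    # joint fit: moment-style start from mean growth, mu a bit below lambda
    r0 = max(1e-4, np.mean(np.log(np.maximum(n, 1.001))) / np.mean(t))
    starts = [(math.log(r0 / 0.5), math.log(r0)),       # eps ~ 0.5
              (math.log(r0), _LOG_RATE_LO + 1.0),        # near pure birth
              (math.log(2 * r0), math.log(1.8 * r0))]    # high turnover
    best = None
    for x0 in starts:
        res = optimize.minimize(
            lambda x: _neg_loglik_arrays(x[0], x[1], n, t), x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun):
        raise RuntimeError("constant-rate ML fit failed to converge: "
                           f"{getattr(best, 'message', 'no trace')}")
    lam = math.exp(best.x[0])
    mu = math.exp(best.x[1])
    boundary = bool(np.any(np.asarray(best.x) < _LOG_RATE_LO + 0.5))
    return ConstantRateFit(params=BDParams(lam, mu), loglik=-best.fun,
                           converged=bool(best.success), at_boundary=boundary,
                           message=str(best.message))
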