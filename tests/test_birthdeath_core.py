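"""Birth-death closed forms against independent oracles.

The main oracle is the matrix exponential of the truncated birth-death
generator (states 0..K), which gives exact transition probabilities for the
lineage-count process without using any of the geometric-form algebra under
test.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from cladeage.birthdeath_core import (
    BDParams,
    ProgenyDistribution,
    expected_richness,
    fit_constant_rate_ml,
    progeny_logpmf,
    progeny_pmf,
    sample_progeny,
    survival_probability,
)
from cladeage.synthetic_data import GeneratorSpec, generate_clade_dataset


def ctmc_pmf(lam: float, mu: float, t: float, n_states: int = 500
             ) -> np.ndarray:
    """Progeny pmf from the truncated CTMC generator (independent oracle)."""
    Q = np.zeros((n_states, n_states))
    for k in range(n_states):
        if k + 1 < n_states:
            Q[k, k + 1] = k * lam
        if k - 1 >= 0:
            Q[k, k - 1] = k * mu
        Q[k, k] = -(k * (lam + mu)) if k + 1 < n_states else -k * mu
    return expm(Q * t)[1]


class TestClosedForms:
    def test_pure_birth_never_dies(self):
        assert survival_probability(BDParams(0.3, 0.0), 200.0) == 1.0

    def test_balanced_survival(self):
        # mu = lambda: P(survival) = 1/(1 + lambda t)
        assert survival_probability(BDParams(0.1, 0.1), 10.0) == \
            pytest.approx(0.5, abs=1e-12)

    def test_survival_matches_ctmc(self):
        p = BDParams(0.2, 0.1)
        oracle = ctmc_pmf(p.lam, p.mu, 30.0)
        assert survival_probability(p, 30.0) == pytest.approx(
            1.0 - oracle[0], abs=1e-8)

    def test_pure_birth_single_survivor(self):
        # P(N=1) = e^{-lambda t}
        assert progeny_pmf(BDParams(0.1, 0.0), 10.0, 1) == pytest.approx(
            math.exp(-1.0), abs=1e-12)

    @pytest.mark.parametrize("lam,mu,t", [
        (0.15, 0.12, 40.0),   # subcritical-ish, high turnover
        (0.1, 0.2, 25.0),     # mu > lambda (declining diversity)
        (0.1, 0.1, 15.0),     # balanced
    ])
    def test_pmf_matches_ctmc(self, lam, mu, t):
        oracle = ctmc_pmf(lam, mu, t)
        ours = progeny_pmf(BDParams(lam, mu), t, np.arange(51))
        np.testing.assert_allclose(ours, oracle[:51], atol=1e-8)

    def test_pmf_normalises_analytically(self):
        # partial sum + exact geometric tail
        p = BDParams(0.2, 0.1)
        t = 30.0
        n = np.arange(0, 2000)
        head = progeny_pmf(p, t, n).sum()
        logp = progeny_logpmf(p, t, 2000)
        b = math.exp(logp - progeny_logpmf(p, t, 1999))
        tail = math.exp(logp) / (1.0 - b)
        assert head + tail == pytest.approx(1.0, abs=1e-12)

    def test_expectation_identities(self):
        p = BDParams(0.1, 0.05)
        t = 50.0
        assert expected_richness(p, t) == pytest.approx(
            math.exp(p.r * t), rel=1e-12)
        cond = expected_richness(p, t, conditioned=True)
        assert cond == pytest.approx(
            math.exp(p.r * t) / survival_probability(p, t), rel=1e-10)
        # conditioned mean equals the pmf mean (partial sum + tail algebra)
        n = np.arange(1, 100000)
        mass = progeny_pmf(p, t, n, conditioned=True)
        assert float((n * mass).sum()) == pytest.approx(cond, rel=1e-9)

    def test_balanced_linear_growth(self):
        # conditioned balanced expectation N(t) = 1 + lambda t
        p = BDParams(99.99, 99.99)
        assert expected_richness(p, 100.0, conditioned=True) == \
            pytest.approx(10_000.0, rel=1e-10)

    def test_continuity_across_r_zero(self):
        t = 20.0
        near = [BDParams(0.1, 0.1 - 1e-12), BDParams(0.1, 0.1),
                BDParams(0.1, 0.1 + 1e-12)]
        surv = [survival_probability(p, t) for p in near]
        cond = [expected_richness(p, t, conditioned=True) for p in near]
        assert max(surv) - min(surv) < 1e-8
        assert (max(cond) - min(cond)) / cond[1] < 1e-8

    def test_trivial_domain(self):
        assert expected_richness(BDParams(0.5, 0.1), 0.0, n0=1) == 1.0
        with pytest.raises(ValueError):
            survival_probability(BDParams(0.1, 0.1), -1.0)
        with pytest.raises(ValueError):
            progeny_logpmf(BDParams(0.1, 0.0), 5.0, 0, conditioned=True)


class TestProperties:
    @given(lam=st.floats(0.001, 5.0), eps=st.floats(0.0, 2.0),
           t=st.floats(0.1, 200.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_survival_is_probability(self, lam, eps, t):
        p = BDParams(lam, eps * lam)
        s = survival_probability(p, t)
        assert 0.0 <= s <= 1.0

    @given(lam=st.floats(0.01, 1.0), eps=st.floats(0.0, 1.5),
           t=st.floats(0.5, 100.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conditioning_never_decreases_mean(self, lam, eps, t):
        p = BDParams(lam, eps * lam)
        cond = expected_richness(p, t, conditioned=True)
        uncond = expected_richness(p, t)
        if p.mu == 0:
            assert cond == pytest.approx(uncond, rel=1e-12)
        elif p.mu * t > 1e-6:
            assert cond > uncond
        else:  # extinction negligible at machine precision
            assert cond >= uncond * (1 - 1e-12)

    def test_survival_decreasing_in_mu_and_t(self):
        lam, t = 0.2, 30.0
        s = [survival_probability(BDParams(lam, mu), t)
             for mu in (0.05, 0.1, 0.2, 0.4)]
        assert all(a > b for a, b in zip(s, s[1:]))
        mu = 0.1
        s = [survival_probability(BDParams(lam, mu), tt)
             for tt in (5.0, 20.0, 80.0, 320.0)]
        assert all(a > b for a, b in zip(s, s[1:]))


class TestSampler:
    def test_degenerate_rates_always_one(self):
        rng = np.random.default_rng(0)
        draws = sample_progeny(BDParams(0.0, 0.0), 10.0, False, rng, size=100)
        assert np.all(draws == 1)

    def test_seed_determinism(self):
        p = BDParams(0.1, 0.05)
        a = sample_progeny(p, 30.0, True, np.random.default_rng(5), size=50)
        b = sample_progeny(p, 30.0, True, np.random.default_rng(5), size=50)
        np.testing.assert_array_equal(a, b)

    def test_frequencies_match_pmf(self):
        # chi-square GOF of 1e5 draws against the analytic pmf
        from scipy.stats import chisquare
        p = BDParams(0.08, 0.04)
        t = 25.0
        rng = np.random.default_rng(11)
        draws = sample_progeny(p, t, True, rng, size=100_000)
        kmax = 30
        observed = np.bincount(np.minimum(draws, kmax + 1))[1:]
        expect = progeny_pmf(p, t, np.arange(1, kmax + 1), conditioned=True)
        expect = np.append(expect, 1.0 - expect.sum())
        observed = np.pad(observed, (0, kmax + 1 - observed.size))
        result = chisquare(observed, expect * draws.size)
        assert result.pvalue > 0.001

    def test_mean_matches_conditioned_expectation(self):
        p = BDParams(0.1, 0.05)
        t = 50.0
        rng = np.random.default_rng(3)
        draws = sample_progeny(p, t, True, rng, size=10 ** 6)
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        target = expected_richness(p, t, conditioned=True)
        assert abs(draws.mean() - target) < 3 * se

    def test_distribution_object_round_trip(self):
        dist = ProgenyDistribution(BDParams(0.1, 0.05), 30.0,
                                   conditioned=True)
        assert dist.p_extinct == 0.0
        assert dist.mean() == pytest.approx(
            expected_richness(dist.params, 30.0, conditioned=True))


class TestMLFit:
    def test_single_clade_grid_search(self):
        # eps fixed at 0, one clade: 1-D optimum vs brute-force grid
        fit = fit_constant_rate_ml(([100], [50.0]), epsilon=0.0)

        def nll(r):
            return -float(progeny_logpmf(BDParams(r, 0.0), 50.0, 100,
                                         conditioned=True))
        grid = minimize_scalar(lambda x: nll(math.exp(x)),
                               bounds=(-10, 2), method="bounded",
                               options={"xatol": 1e-12})
        assert fit.params.r == pytest.approx(math.exp(grid.x), abs=1e-6)

    def test_no_growth_signal_flags_boundary(self):
        fit = fit_constant_rate_ml(([1] * 20, [10.0] * 20), epsilon=0.0)
        assert fit.at_boundary

    def test_parameter_recovery(self):
        # moderately sized recovery study; truth within 3 SE of the mean
        lam_hat, mu_hat = [], []
        for seed in range(20):
            spec = GeneratorSpec(n_tips=300, richness_model="constant_rate",
                                 lam=0.7, mu=0.6, backbone_lam=0.05,
                                 seed=seed)
            ds, _ = generate_clade_dataset(spec)
            fit = fit_constant_rate_ml(ds)
            lam_hat.append(fit.params.lam)
            mu_hat.append(fit.params.mu)
        for est, truth in ((lam_hat, 0.7), (mu_hat, 0.6)):
            arr = np.array(est)
            se = arr.std(ddof=1) / math.sqrt(arr.size)
            assert abs(arr.mean() - truth) < 3 * se + 0.05
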