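"""Two-state higher-taxon simulator and its Spearman null distribution."""

import math

import numpy as np
import pytest
from scipy import stats

from cladeage.birthdeath_core import BDParams
from cladeage.clade_data import CladeDataset, CladeRecord
from cladeage.higher_taxon_sim import (
    NullDistribution,
    SimConfig,
    build_null,
    simulate_higher_taxon_tree,
    spearman,
)
from cladeage.synthetic_data import GeneratorSpec, generate_clade_dataset

WIDE = dict(rejection_low=1e-3, rejection_high=1e3)


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_ties_match_brute_force_ranks(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, 40).astype(float)
        y = rng.integers(0, 5, 40).astype(float)
        rho = spearman(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expect = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expect, abs=1e-12)

    def test_constant_vector_flagged(self):
        assert math.isnan(spearman([1, 1, 1], [1, 2, 3]))


class TestSimulator:
    def test_seed_determinism(self):
        cfg = SimConfig(crown_age=80.0, rate_class_pool=[BDParams(0.05,
                                                                  0.01)],
                        observed_n_terminals=40, **WIDE)
        a = simulate_higher_taxon_tree(cfg, np.random.default_rng(7))
        b = simulate_higher_taxon_tree(cfg, np.random.default_rng(7))
        assert (a is None) == (b is None)
        if a is not None:
            assert a.tree.as_newick() == b.tree.as_newick()
            np.testing.assert_array_equal(a.richness, b.richness)

    def test_pure_birth_every_terminal_counted(self):
        # no extinction: total species >= number of terminals
        cfg = SimConfig(crown_age=60.0, rate_class_pool=[BDParams(0.05,
                                                                  0.0)],
                        observed_n_terminals=30, **WIDE)
        rng = np.random.default_rng(1)
        accepted = 0
        for _ in range(200):
            sim = simulate_higher_taxon_tree(cfg, rng)
            if sim is None:  # fewer than 3 surviving terminals
                continue
            accepted += 1
            assert np.all(sim.richness >= 1)
            assert sim.richness.sum() >= sim.n_terminals
            if accepted == 10:
                break
        assert accepted == 10

    def test_no_events_only_two_lineages(self):
        # phi = 0 fixed and no death/shift: the two starting lineages
        # survive unconverted
        cfg = SimConfig(crown_age=50.0, rate_class_pool=[BDParams(0.0, 0.0)],
                        phi_policy=0.0, observed_n_terminals=2, **WIDE)
        sim = simulate_higher_taxon_tree(cfg, np.random.default_rng(0))
        assert sim is None or sim.n_terminals == 2  # < 3 tips -> rejected
        # with no taxon formation both terminals are richness-1 lineages

    def test_branching_mean_matches_exponential_growth(self):
        # pure lineage growth (phi = 0): terminal count is the sum of two
        # independent Yule populations.  The simulator discards trees with
        # fewer than 3 terminals, so the oracle is the conditional mean
        # E[N | N >= 3] = (2 e^{lam T} - 2 p^2) / (1 - p^2), p = e^{-lam T}
        lam, T = 0.03, 60.0
        cfg = SimConfig(crown_age=T, rate_class_pool=[BDParams(lam, 0.0)],
                        phi_policy=0.0, observed_n_terminals=10, **WIDE)
        rng = np.random.default_rng(3)
        counts = []
        for _ in range(1500):
            sim = simulate_higher_taxon_tree(cfg, rng)
            if sim is not None:
                counts.append(sim.n_terminals)
        counts = np.array(counts)
        p = math.exp(-lam * T)
        target = (2 * math.exp(lam * T) - 2 * p ** 2) / (1 - p ** 2)
        se = counts.std(ddof=1) / math.sqrt(counts.size)
        assert abs(counts.mean() - target) < 3 * se

    def test_rejection_bounds_exact(self):
        cfg = SimConfig(crown_age=100.0,
                        rate_class_pool=[BDParams(0.06, 0.02)],
                        observed_n_terminals=50)
        rng = np.random.default_rng(5)
        accepted = 0
        for _ in range(400):
            sim = simulate_higher_taxon_tree(cfg, rng)
            if sim is not None:
                accepted += 1
                assert 25 <= sim.n_terminals <= 75
        assert accepted > 0

    def test_taxon_richness_exchangeable_with_direct_draw(self):
        # formation at T1 with rates (lam, mu) must give the same richness
        # law as a direct unconditioned progeny draw over T - T1, dropping
        # zeros (taxa that died); KS on collected taxa vs direct sample
        from cladeage.birthdeath_core import sample_progeny
        lam, mu, T = 0.08, 0.03, 50.0
        cfg = SimConfig(crown_age=T, rate_class_pool=[BDParams(lam, mu)],
                        observed_n_terminals=30, **WIDE)
        rng = np.random.default_rng(8)
        taxa_rich, taxa_t1 = [], []
        while len(taxa_rich) < 2000:
            sim = simulate_higher_taxon_tree(cfg, rng)
            if sim is None:
                continue
            for r, s, t1 in zip(sim.richness, sim.states,
                                sim.formation_times):
                if s == "higher_taxon":
                    taxa_rich.append(r)
                    taxa_t1.append(t1)
        direct = []
        rng2 = np.random.default_rng(9)
        for t1 in taxa_t1:
            d = sample_progeny(BDParams(lam, mu), T - t1, False, rng2)
            if d > 0:
                direct.append(d)
        res = stats.ks_2samp(np.array(taxa_rich), np.array(direct))
        assert res.pvalue > 0.001


def _self_simulated_observed(cfg: SimConfig, seed: int) -> CladeDataset:
    rng = np.random.default_rng(seed)
    while True:
        sim = simulate_higher_taxon_tree(cfg, rng)
        if sim is not None:
            records = [CladeRecord(nm, int(r)) for nm, r in
                       zip(sim.tree.tip_labels, sim.richness)]
            return CladeDataset(tree=sim.tree, records=records)


class TestNull:
    CFG = dict(crown_age=80.0, rate_class_pool=[BDParams(0.06, 0.02)],
               observed_n_terminals=40, n_accepted_target=200)

    def test_constant_rate_pool_positive_mean_rho(self):
        cfg = SimConfig(**self.CFG)
        observed = _self_simulated_observed(cfg, seed=1)
        null = build_null(cfg, observed, seed=2)
        assert null.summary()["rho_mean"] > 0.2

    def test_mean_rho_increases_with_terminal_count(self):
        means = []
        for n_obs, crown in ((15, 60.0), (60, 100.0)):
            cfg = SimConfig(crown_age=crown,
                            rate_class_pool=[BDParams(0.06, 0.02)],
                            observed_n_terminals=n_obs,
                            n_accepted_target=150)
            observed = _self_simulated_observed(cfg, seed=3)
            null = build_null(cfg, observed, seed=4)
            means.append(null.summary()["rho_mean"])
        assert means[1] > means[0]

    def test_rate_heterogeneity_lowers_mean_rho(self):
        homo = SimConfig(crown_age=80.0,
                         rate_class_pool=[BDParams(0.06, 0.02)],
                         observed_n_terminals=40, n_accepted_target=300)
        hetero = SimConfig(crown_age=80.0,
                           rate_class_pool=[BDParams(0.02, 0.0),
                                            BDParams(0.25, 0.05)],
                           alpha=0.02, observed_n_terminals=40,
                           n_accepted_target=300)
        obs = _self_simulated_observed(homo, seed=5)
        rho_homo = build_null(homo, obs, seed=6).summary()["rho_mean"]
        rho_het = build_null(hetero, obs, seed=6).summary()["rho_mean"]
        assert rho_het < rho_homo

    def test_p_tail_definition(self):
        # monotone observed data vs a weak null: p should be large when the
        # observed rho sits in the null's upper tail
        cfg = SimConfig(**self.CFG)
        spec = GeneratorSpec(n_tips=40, richness_model="constant_rate",
                             lam=0.08, mu=0.0, crown_age=80.0, seed=7)
        observed, _ = generate_clade_dataset(spec)
        null = build_null(cfg, observed, seed=8)
        manual = (1 + np.sum(null.rho <= null.observed_rho)) / (1 +
                                                                null.rho.size)
        assert null.p_lower == pytest.approx(manual)

    def test_calibration_p_uniform_under_self_simulation(self):
        cfg = SimConfig(crown_age=60.0,
                        rate_class_pool=[BDParams(0.07, 0.02)],
                        observed_n_terminals=25, n_accepted_target=99)
        ps = []
        for k in range(60):
            observed = _self_simulated_observed(cfg, seed=100 + k)
            null = build_null(cfg, observed, seed=500 + k)
            ps.append(null.p_lower)
        res = stats.kstest(ps, "uniform")
        assert res.pvalue > 0.001
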