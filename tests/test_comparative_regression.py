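"""PGLS/OLS regression, Pagel's lambda, contrasts tests and subtree scans."""

import math

import numpy as np
import pytest

from cladeage.clade_data import CladeDataset, CladeRecord, TimeTree
from cladeage.comparative_regression import (
    contrasts_signal_test,
    estimate_lambda,
    independent_contrasts,
    pgls_fit,
    scan_subtrees,
    subset_by_age,
)
from cladeage.synthetic_data import (
    GeneratorSpec,
    generate_clade_dataset,
    generate_timetree,
)


def make_dataset(newick: str, richness: dict) -> CladeDataset:
    tree = TimeTree.from_newick(newick)
    records = [CladeRecord(n, richness[n]) for n in tree.tip_labels]
    return CladeDataset(tree=tree, records=records)


class TestPglsFit:
    def test_star_tree_equals_ols(self, star_dataset):
        # V is proportional to the identity on a star tree; a varying
        # predictor is supplied because every stem age equals the root age
        x = np.linspace(3.0, 40.0, star_dataset.n_clades)
        bm = pgls_fit(star_dataset, covariance_model="BM", predictor=x)
        ols = pgls_fit(star_dataset, covariance_model="identity",
                       predictor=x)
        assert bm.slope == pytest.approx(ols.slope, abs=1e-10)
        assert bm.t_statistic == pytest.approx(ols.t_statistic, abs=1e-10)
        assert bm.p_value == pytest.approx(ols.p_value, abs=1e-10)

    def test_lambda_zero_transform_equals_ols_slope(self,
                                                    constant_rate_dataset):
        lam0 = pgls_fit(constant_rate_dataset, covariance_model="lambda",
                        lambda_value=0.0)
        ols = pgls_fit(constant_rate_dataset, covariance_model="identity")
        # lambda = 0 keeps the (equal, ultrametric) diagonal: V = h * I
        assert lam0.slope == pytest.approx(ols.slope, abs=1e-10)
        assert lam0.t_statistic == pytest.approx(ols.t_statistic, abs=1e-8)

    def test_constant_response_zero_slope(self, three_tip_tree):
        ds = CladeDataset(tree=three_tip_tree,
                          records=[CladeRecord(n, 7) for n in "ABC"])
        fit = pgls_fit(ds)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.t_statistic == 0.0

    def test_four_tip_hand_computed_gls(self):
        ds = make_dataset("((A:2,B:2):8,(C:6,D:6):4);",
                          {"A": 3, "B": 11, "C": 40, "D": 7})
        fit = pgls_fit(ds)
        # explicit matrix arithmetic oracle
        V = ds.tree.vcv(order=ds.names)
        x = ds.stem_age_array()
        y = np.log(ds.richness_array().astype(float))
        X = np.column_stack([np.ones(4), x])
        Vi = np.linalg.inv(V)
        beta = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
        resid = y - X @ beta
        sigma2 = resid @ Vi @ resid / 2
        se = math.sqrt((sigma2 * np.linalg.inv(X.T @ Vi @ X))[1, 1])
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.t_statistic == pytest.approx(beta[1] / se, abs=1e-10)
        assert fit.df == 2

    def test_slope_rescales_with_time_units(self, constant_rate_dataset):
        fit = pgls_fit(constant_rate_dataset)
        # uniform 2x stretch of branch lengths halves the slope, keeps t, p
        stretched = constant_rate_dataset.tree.clone()
        for e in stretched.dendropy_tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= 2.0
        ds2 = CladeDataset(tree=stretched,
                           records=[CladeRecord(r.name, r.richness)
                                    for r in constant_rate_dataset.records])
        fit2 = pgls_fit(ds2)
        assert fit2.slope == pytest.approx(fit.slope / 2.0, rel=1e-9)
        assert fit2.t_statistic == pytest.approx(fit.t_statistic, rel=1e-9)
        assert fit2.p_value == pytest.approx(fit.p_value, rel=1e-9)

    def test_log_base_option(self, constant_rate_dataset):
        e_fit = pgls_fit(constant_rate_dataset)
        ten = pgls_fit(constant_rate_dataset, log_base=10.0)
        assert ten.slope == pytest.approx(e_fit.slope / math.log(10),
                                          rel=1e-10)


class TestEstimateLambda:
    def test_bm_data_recovers_high_lambda(self):
        hits = 0
        for seed in range(15):
            spec = GeneratorSpec(n_tips=200, richness_model="bm_signal_only",
                                 Lambda=1.0, seed=seed)
            ds, truth = generate_clade_dataset(spec)
            sig = estimate_lambda(ds, values=np.array(truth["log_values"]))
            hits += sig.Lambda_ml > 0.8
        assert hits >= 14  # >= ~95% of replicates

    def test_iid_noise_prefers_lambda_zero(self):
        tree = generate_timetree(200, seed=1)
        rng = np.random.default_rng(0)
        records = [CladeRecord(n, 2) for n in tree.tip_labels]
        ds = CladeDataset(tree=tree, records=records)
        sig = estimate_lambda(ds, values=rng.normal(size=200))
        assert sig.Lambda_ml < 0.2
        assert sig.delta_aic < 2.0  # no support for the lambda model


class TestContrasts:
    def test_contrast_count_and_zero_variance(self, balanced16_tree):
        records = [CladeRecord(n, 5) for n in balanced16_tree.tip_labels]
        ds = CladeDataset(tree=balanced16_tree, records=records)
        pics = independent_contrasts(ds)
        assert pics.size == 15  # n - 1 contrasts on a binary tree
        assert np.allclose(pics, 0.0)
        res = contrasts_signal_test(ds, n_permutations=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_bm_data_detected(self):
        hits = 0
        for seed in range(10):
            spec = GeneratorSpec(n_tips=200, richness_model="bm_signal_only",
                                 Lambda=1.0, seed=100 + seed)
            ds, truth = generate_clade_dataset(spec)
            res = contrasts_signal_test(
                ds, n_permutations=99, values=np.array(truth["log_values"]),
                seed=seed)
            hits += res.p_value <= 0.05
        assert hits >= 9

    def test_iid_values_null_calibration(self):
        tree = generate_timetree(80, seed=2)
        records = [CladeRecord(n, 2) for n in tree.tip_labels]
        ds = CladeDataset(tree=tree, records=records)
        rng = np.random.default_rng(1)
        ps = [contrasts_signal_test(ds, n_permutations=59,
                                    values=rng.normal(size=80),
                                    seed=k).p_value
              for k in range(40)]
        # roughly uniform: mean near 0.5, not piled at either end
        assert 0.3 < np.mean(ps) < 0.7

    def test_analytic_mode_resolves_extreme_p(self):
        spec = GeneratorSpec(n_tips=300, richness_model="bm_signal_only",
                             Lambda=1.0, seed=9)
        ds, truth = generate_clade_dataset(spec)
        res = contrasts_signal_test(ds, n_permutations=199, mode="analytic",
                                    values=np.array(truth["log_values"]),
                                    seed=3)
        assert res.p_value < 1 / 200  # below the permutation floor


class TestScanAndSubset:
    def test_balanced_16_single_qualifying_subtree(self, balanced16_tree):
        rng = np.random.default_rng(4)
        records = [CladeRecord(n, int(rng.integers(1, 50)))
                   for n in balanced16_tree.tip_labels]
        ds = CladeDataset(tree=balanced16_tree, records=records)
        res = scan_subtrees(ds, min_tips=10)
        assert res.n_subtrees == 1  # only the root holds >= 10 tips

    def test_constant_rate_positive_slopes_dominate(self):
        spec = GeneratorSpec(n_tips=200, richness_model="constant_rate",
                             lam=0.1, mu=0.05, seed=12)
        ds, _ = generate_clade_dataset(spec)
        res = scan_subtrees(ds, min_tips=10)
        assert res.n_significant_positive > res.n_significant_negative
        table = res.table.dropna()
        assert (table["slope"] > 0).mean() > 0.5

    def test_exclusion_removes_tips(self):
        spec = GeneratorSpec(n_tips=60, richness_model="constant_rate",
                             seed=3)
        ds, _ = generate_clade_dataset(spec)
        drop = ds.names[:20]
        res = scan_subtrees(ds, min_tips=10, exclude=drop)
        assert res.excluded_tips == drop
        assert res.table["n_tips"].max() <= 40

    def test_subset_by_age_matches_direct_filter(self):
        spec = GeneratorSpec(n_tips=100, richness_model="constant_rate",
                             seed=5)
        ds, _ = generate_clade_dataset(spec)
        max_age = float(np.median(ds.stem_age_array()))
        sub = subset_by_age(ds, max_age)
        expect = [n for n, a in zip(ds.names, ds.stem_age_array())
                  if a < max_age]
        assert sorted(sub.names) == sorted(expect)

    def test_subset_above_root_is_identity(self, constant_rate_dataset):
        sub = subset_by_age(constant_rate_dataset, 1e9)
        assert sub is constant_rate_dataset

    def test_subset_empty_errors(self, constant_rate_dataset):
        with pytest.raises(ValueError):
            subset_by_age(constant_rate_dataset, 1e-9)
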