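"""Cohort statistics: rank-sum and G tests against enumeration oracles,
quartiles, PCA variance profile, hierarchical-clustering order."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metaborank import (
    SyntheticConfig,
    generate_cohort,
    group_median_iqr,
    hierarchical_cluster_order,
    likelihood_ratio_chi2,
    pca_variance_profile,
    run_preprocessing,
    univariate_metabolite_table,
    wilcoxon_rank_sum,
)


class TestWilcoxonRankSum:
    def test_extreme_ordering_exact_p(self):
        # all C(6,3)=20 labelings: the observed rank sum is one of the 2 most
        # extreme, so the exact two-sided p is 2/20 = 0.1
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_exact_p_matches_full_enumeration(self):
        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 9.0, 11.0]
        stat, p = wilcoxon_rank_sum(a, b)
        # oracle: enumerate every assignment of the 7 ranks to group A
        combined = np.array(a + b)
        ranks = sps.rankdata(combined)
        observed = ranks[:3].sum()
        mean_rs = 3 * (7 + 1) / 2
        count = sum(
            abs(sum(ranks[list(idx)]) - mean_rs) >= abs(observed - mean_rs) - 1e-12
            for idx in itertools.combinations(range(7), 3)
        )
        assert p == pytest.approx(count / math.comb(7, 3), abs=1e-12)

    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        _, p = wilcoxon_rank_sum(x, x)
        assert p > 0.95

    def test_normal_approximation_close_to_exact_at_n12(self):
        rng = np.random.default_rng(1)
        for _ in range(12):
            vals = rng.permutation(np.arange(1.0, 13.0))
            a, b = vals[:6], vals[6:]
            _, p_exact = wilcoxon_rank_sum(a, b)  # n<=12, no ties -> exact path
            p_norm = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            assert abs(p_exact - min(p_norm, 1.0)) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestLikelihoodRatioChi2:
    def test_respiratory_failure_style_counts(self):
        # survivors 27/35 vs non-survivors 24/25 with respiratory failure
        g, p = likelihood_ratio_chi2([[27, 8], [24, 1]])
        assert 0.02 < p < 0.04
        assert g == pytest.approx(4.6998, abs=1e-3)

    def test_table_proportional_to_margins_gives_null(self):
        g, p = likelihood_ratio_chi2([[10, 20], [20, 40]])
        assert g == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_transpose_invariance(self):
        t = [[7, 13], [19, 3]]
        g1, _ = likelihood_ratio_chi2(t)
        g2, _ = likelihood_ratio_chi2(np.transpose(t))
        assert g1 == pytest.approx(g2, abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            obs = rng.integers(1, 40, size=(2, 2)).astype(float)
            g, _ = likelihood_ratio_chi2(obs)
            expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            oracle = 2 * sum(
                o * math.log(o / e) for o, e in zip(obs.ravel(), expected.ravel()) if o > 0
            )
            assert g == pytest.approx(oracle, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            likelihood_ratio_chi2([[0, 0], [5, 3]])


class TestGroupMedianIqr:
    def test_one_to_five(self):
        out = group_median_iqr([1, 2, 3, 4, 5, 10, 20, 30], [0] * 5 + [1] * 3)
        assert out.loc[0].tolist() == [3.0, 2.0, 4.0]

    def test_single_value_group(self):
        out = group_median_iqr([7.0, 1.0, 2.0], [1, 0, 0])
        assert out.loc[1].tolist() == [7.0, 7.0, 7.0]

    def test_matches_sort_interpolate_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=40)
        y = np.array([0] * 25 + [1] * 15)
        out = group_median_iqr(vals, y)

        def oracle_quantile(x, q):
            x = np.sort(x)
            pos = q * (len(x) - 1)
            lo = int(math.floor(pos))
            hi = min(lo + 1, len(x) - 1)
            return x[lo] + (pos - lo) * (x[hi] - x[lo])

        for g in (0, 1):
            gv = vals[y == g]
            assert out.loc[g, "q1"] == pytest.approx(oracle_quantile(gv, 0.25), abs=1e-12)
            assert out.loc[g, "median"] == pytest.approx(oracle_quantile(gv, 0.5), abs=1e-12)
            assert out.loc[g, "q3"] == pytest.approx(oracle_quantile(gv, 0.75), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_median_iqr([1.0, 2.0], [0, 0])


class TestPcaVarianceProfile:
    def test_rank_one_matrix(self):
        u = np.arange(1.0, 9.0)
        v = np.array([2.0, -1.0, 0.5])
        profile = pca_variance_profile(np.outer(u, v), standardize=False)
        assert profile.fractions[0] == pytest.approx(1.0, abs=1e-12)
        assert profile.n_components_for(0.8) == 1

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        profile = pca_variance_profile(rng.normal(size=(30, 10)))
        assert profile.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(profile.cumulative) >= -1e-12)

    def test_isotropic_noise_near_uniform_fractions(self):
        rng = np.random.default_rng(5)
        profile = pca_variance_profile(rng.normal(size=(4000, 5)))
        np.testing.assert_allclose(profile.fractions, np.full(5, 0.2), atol=0.03)

    def test_block_correlation_concentrates_variance(self):
        shape = dict(n_samples=60, n_metabolites=100, n_pathways=4, n_effect_metabolites=0)
        correlated = generate_cohort(SyntheticConfig(within_pathway_correlation=0.4, seed=6, **shape))
        independent = generate_cohort(SyntheticConfig(within_pathway_correlation=0.0, seed=6, **shape))
        k_corr = pca_variance_profile(np.log10(correlated.table.values)).n_components_for(0.8)
        k_ind = pca_variance_profile(np.log10(independent.table.values)).n_components_for(0.8)
        assert k_corr < k_ind

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca_variance_profile(np.ones((5, 3)), standardize=False)


class TestHierarchicalClusterOrder:
    def test_identical_pair_adjacent(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0]])
        order = list(hierarchical_cluster_order(X))
        pos0, pos2 = order.index(0), order.index(2)
        assert abs(pos0 - pos2) == 1

    def test_three_point_line_complete_linkage(self):
        # points at 0, 1, 3: complete linkage merges {0,1} first (d=1), then
        # joins 2 at distance max(3,2)=3
        X = np.array([[0.0], [1.0], [3.0]])
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import pdist

        Z = hierarchy.linkage(pdist(X), method="complete")
        assert sorted(Z[0, :2].astype(int).tolist()) == [0, 1]
        assert Z[1, 2] == pytest.approx(3.0)
        order = list(hierarchical_cluster_order(X))
        assert abs(order.index(0) - order.index(1)) == 1  # merged pair adjacent

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 4))
        a = hierarchical_cluster_order(X)
        b = hierarchical_cluster_order(X)
        np.testing.assert_array_equal(a, b)

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster_order(np.ones((1, 3)))


class TestUnivariateTable:
    def test_null_cohort_pvalues_near_uniform(self):
        cfg = SyntheticConfig(
            n_effect_metabolites=0, within_pathway_correlation=0.0, seed=8
        )
        cohort = generate_cohort(cfg)
        table, _ = run_preprocessing(cohort.table)
        out = univariate_metabolite_table(table, cohort.metadata.outcome)
        ks = sps.kstest(out["p_value"].to_numpy(), "uniform").statistic
        assert ks <= 0.1

    def test_medians_reported_on_raw_scale(self, small_cohort):
        table, _ = run_preprocessing(small_cohort.table)
        out = univariate_metabolite_table(table, small_cohort.metadata.outcome)
        assert (out["median_survived"] > 10).all()  # ion-count magnitudes, not log10
        assert (out["q1_survived"] <= out["median_survived"]).all()
        assert (out["median_survived"] <= out["q3_survived"]).all()
        assert out["p_value"].between(0, 1).all()
        assert (out["p_adjusted_bh"] >= out["p_value"] - 1e-12).all()
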