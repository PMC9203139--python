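"""Cross-validation engine: fold plans, PR/ROC metrics against brute-force
oracles, fold-safe preprocessing, and grid tuning."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from metaborank import (
    CVConfig,
    PreprocessConfig,
    confusion_metrics,
    default_registry,
    log10_transform,
    make_fold_plan,
    pr_auc,
    prepare_fold_data,
    roc_auc,
    tune_model,
)

from conftest import make_table

# ---------------------------------------------------------------------------
# independent oracles: brute-force enumeration over all score thresholds


def ap_oracle(scores, labels):
    """Average precision by explicit enumeration of distinct thresholds."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def auc_oracle(scores, labels):
    """ROC AUC by counting concordant positive-negative pairs (ties half)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


@st.composite
def small_instance(draw):
    n = draw(st.integers(min_value=2, max_value=12))
    labels = draw(
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ls: 0 < sum(ls) < len(ls)
        )
    )
    # coarse score grid so ties actually occur
    scores = draw(st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=n, max_size=n))
    return np.array(scores), np.array(labels)


class TestMetricsAgainstOracles:
    @given(small_instance())
    def test_pr_auc_equals_brute_force(self, inst):
        scores, labels = inst
        assert pr_auc(scores, labels) == pytest.approx(ap_oracle(scores, labels), abs=1e-12)

    @given(small_instance())
    def test_roc_auc_equals_brute_force(self, inst):
        scores, labels = inst
        assert roc_auc(scores, labels) == pytest.approx(auc_oracle(scores, labels), abs=1e-12)

    def test_perfect_ordering(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        assert pr_auc(scores, labels) == 1.0
        assert roc_auc(scores, labels) == 1.0

    def test_constant_scores_give_prevalence(self):
        labels = np.array([1] * 25 + [0] * 35)
        scores = np.full(60, 0.5)
        assert pr_auc(scores, labels) == pytest.approx(25 / 60, abs=1e-12)

    def test_worked_example(self):
        # thresholds: at 0.9 -> P=1, R=1/2; at 0.7 -> P=2/3, R=1
        assert pr_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(
            0.5 * 1.0 + 0.5 * (2 / 3), abs=1e-12
        )
        # 3 of 4 positive-negative pairs concordant
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_reversed_scores_complement(self):
        rng = np.random.default_rng(0)
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        assert roc_auc(-s, y) == pytest.approx(1 - roc_auc(s, y), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [0, 0])


class TestConfusionMetrics:
    def test_all_correct(self):
        assert confusion_metrics([0.9, 0.1], [1, 0], 0.5) == (1.0, 1.0)

    def test_worked_example(self):
        sens, spec = confusion_metrics([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0], 0.5)
        assert (sens, spec) == (0.5, 0.5)

    def test_threshold_zero_full_sensitivity(self):
        sens, _ = confusion_metrics([0.0, 0.3], [1, 0], 0.0)
        assert sens == 1.0

    def test_no_positives_warns_nan(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            sens, spec = confusion_metrics([0.2, 0.7], [0, 0], 0.5)
        assert np.isnan(sens) and spec == 0.5


class TestFoldPlan:
    def test_study_dimensions_exact_stratification(self):
        y = pd.Series([1] * 25 + [0] * 35, index=[f"S{i}" for i in range(60)])
        plan = make_fold_plan(y, CVConfig(n_folds=5, n_repeats=2, seed=0))
        for fa in plan:
            assert len(fa.test_ids) == 12  # 60 / 5
            assert sum(y[list(fa.test_ids)]) == 5  # 25 / 5

    def test_default_config_yields_250_splits(self):
        y = pd.Series([1] * 25 + [0] * 35, index=range(60))
        plan = make_fold_plan(y, CVConfig(seed=1))
        assert len(plan) == 250  # 50 repeats x 5 folds

    def test_partition_within_each_repeat(self):
        y = pd.Series([1] * 10 + [0] * 17, index=[f"S{i}" for i in range(27)])
        plan = make_fold_plan(y, CVConfig(n_folds=3, n_repeats=4, seed=3))
        for r in range(4):
            tests = [set(fa.test_ids) for fa in plan if fa.repeat_index == r]
            assert set().union(*tests) == set(y.index)
            for i in range(len(tests)):
                assert set(plan.folds[3 * r + i].train_ids).isdisjoint(tests[i])
                for j in range(i + 1, len(tests)):
                    assert tests[i].isdisjoint(tests[j])

    def test_deterministic_given_seed(self):
        y = pd.Series([1] * 8 + [0] * 12, index=range(20))
        a = make_fold_plan(y, CVConfig(n_folds=4, n_repeats=3, seed=5))
        b = make_fold_plan(y, CVConfig(n_folds=4, n_repeats=3, seed=5))
        assert a.folds == b.folds

    def test_class_smaller_than_folds_rejected(self):
        y = pd.Series([1] * 3 + [0] * 20)
        with pytest.raises(ValueError):
            make_fold_plan(y, CVConfig(n_folds=5, n_repeats=1))


def _noise_table_and_outcome(seed=0, n=30, p=12, n_masked=6):
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(mean=1.0, size=(n, p))
    mask = np.zeros((n, p), bool)
    flat = rng.choice(n * p, size=n_masked, replace=False)
    mask[np.unravel_index(flat, (n, p))] = True
    table = log10_transform(make_table(vals, mask=mask))
    y = pd.Series(rng.permutation(np.repeat([0, 1], [n - n // 3, n // 3])), index=table.sample_ids)
    return table, y


class TestFoldSafePreprocessing:
    def test_corrupting_test_values_leaves_train_preprocessing_unchanged(self):
        table, y = _noise_table_and_outcome(seed=2)
        cfg = CVConfig(n_folds=3, n_repeats=1, seed=2)
        plan = make_fold_plan(y, cfg)
        before = prepare_fold_data(table, y, plan)
        corrupted = table.copy()
        test_ids = list(plan.folds[0].test_ids)
        corrupted.values.loc[test_ids] *= 100.0
        after = prepare_fold_data(corrupted, y, plan)
        # fold 0's own training preprocessing must not see its test rows
        # (those same rows are legitimate training data in the other folds)
        pd.testing.assert_frame_equal(before[0].X_train, after[0].X_train)
        assert not before[0].X_test.equals(after[0].X_test)

    def test_imputation_fill_comes_from_train_folds_only(self):
        table, y = _noise_table_and_outcome(seed=4)
        plan = make_fold_plan(y, CVConfig(n_folds=3, n_repeats=1, seed=4))
        fold_data = prepare_fold_data(
            table, y, plan, PreprocessConfig(scaling="none")
        )
        fa, fd = plan.folds[0], fold_data[0]
        v_train = table.values.loc[list(fa.train_ids)]
        m_train = table.below_lod.loc[list(fa.train_ids)]
        for mid in table.metabolite_ids:
            observed_min = v_train[mid][~m_train[mid]].min()
            m_test = table.below_lod.loc[list(fa.test_ids), mid]
            if m_test.any():
                filled = fd.X_test.loc[m_test[m_test].index, mid]
                assert (filled == observed_min / 2).all()


class TestTuneModel:
    def _spec(self, family, grid=None):
        spec = next(s for s in default_registry() if s.family_id == family)
        if grid is not None:
            spec.grid = grid
        return spec

    def test_one_point_grid_selected(self):
        table, y = _noise_table_and_outcome(seed=1)
        cfg = CVConfig(n_folds=3, n_repeats=1, seed=1)
        plan = make_fold_plan(y, cfg)
        spec = self._spec("lasso_logistic", [{"C": 0.5}])
        res = tune_model(spec, table, y, plan, cfg)
        assert res.best_hyperparams == {"C": 0.5}

    def test_dominant_grid_point_wins_on_separable_data(self):
        rng = np.random.default_rng(6)
        n, p = 40, 8
        y_arr = rng.permutation(np.repeat([0, 1], n // 2))
        vals = rng.lognormal(size=(n, p))
        vals[:, 0] = np.power(10.0, y_arr + rng.normal(scale=0.05, size=n))
        table = log10_transform(make_table(vals))
        y = pd.Series(y_arr, index=table.sample_ids)
        cfg = CVConfig(n_folds=4, n_repeats=2, seed=6)
        plan = make_fold_plan(y, cfg)
        # C=1e-5 is intercept-only (no-skill); C=1.0 separates
        spec = self._spec("lasso_logistic", [{"C": 1e-5}, {"C": 1.0}])
        res = tune_model(spec, table, y, plan, cfg)
        assert res.best_hyperparams == {"C": 1.0}

    def test_tie_prefers_simpler_grid_point(self):
        rng = np.random.default_rng(8)
        n = 32
        y_arr = rng.permutation(np.repeat([0, 1], n // 2))
        vals = np.power(10.0, np.column_stack([y_arr * 3.0 + 1, y_arr * 3.0 + 1.2,
                                               rng.normal(1, 0.2, n)]))
        table = log10_transform(make_table(vals))
        y = pd.Series(y_arr, index=table.sample_ids)
        cfg = CVConfig(n_folds=4, n_repeats=1, seed=8)
        plan = make_fold_plan(y, cfg)
        # both penalties separate this perfectly -> exact tie -> first entry wins
        spec = self._spec("lasso_logistic", [{"C": 0.5}, {"C": 10.0}])
        res = tune_model(spec, table, y, plan, cfg)
        assert res.best_hyperparams == {"C": 0.5}

    def test_metric_vector_shape_and_range(self):
        table, y = _noise_table_and_outcome(seed=3)
        cfg = CVConfig(n_folds=3, n_repeats=2, seed=3)
        plan = make_fold_plan(y, cfg)
        spec = self._spec("lasso_logistic", [{"C": 0.5}])
        res = tune_model(spec, table, y, plan, cfg)
        assert len(res.fold_metrics) == 6  # n_folds x n_repeats
        for col in ("pr_auc", "roc_auc"):
            assert res.fold_metrics[col].between(0, 1).all()

    def test_noise_selection_stays_sparse_with_one_se_rule(self):
        # sparse families on pure noise: the one-SE grid rule keeps the tuned
        # native selections far below the planted-signal regime
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            vals = rng.lognormal(mean=1.0, size=(60, 40))
            table = log10_transform(make_table(vals))
            y = pd.Series(
                rng.permutation(np.repeat([0, 1], [35, 25])), index=table.sample_ids
            )
            cfg = CVConfig(n_folds=5, n_repeats=2, seed=seed)
            plan = make_fold_plan(y, cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = tune_model(
                    self._spec("nearest_shrunken_centroids"), table, y, plan, cfg
                )
            counts.append(len(res.selected_ids))
        assert np.median(counts) <= 0.2 * 40

    def test_tuned_lasso_beats_no_skill_on_planted_cohort(self, small_cohort):
        from metaborank import run_preprocessing, exclude_drug_metabolites, filter_below_lod

        table, _ = exclude_drug_metabolites(small_cohort.table)
        table, _ = filter_below_lod(table, PreprocessConfig())
        table = log10_transform(table)
        y = small_cohort.metadata.outcome
        cfg = CVConfig(n_folds=5, n_repeats=3, seed=0)
        plan = make_fold_plan(y, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = tune_model(self._spec("lasso_logistic"), table, y, plan, cfg)
        prevalence = y.mean()
        assert res.fold_metrics["pr_auc"].mean() > prevalence

    def test_empty_grid_rejected(self):
        from metaborank import ModelSpec

        with pytest.raises(ValueError, match="non-empty"):
            ModelSpec("lasso_logistic", [], "native")
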