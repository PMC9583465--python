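"""Evaluation harness: univariate AUC, nested CV, RFE, group statistics."""

import numpy as np
import pandas as pd
import pytest

from oscml import REGISTRY, group_compare, nested_cv, rfe_select, univariate_auc
from oscml.evaluation import (
    ANALYSES, N_OUTER_FOLDS, analysis_subset, lr_weight_average, plan_experiment,
    rfe_path, selection_frequency,
)
from oscml.fuzzify import fit_scheme

SMALL_LR = REGISTRY["LR"].with_grid({"C": [0.1, 1, 10]})


def _signal_dataset(n=60, n_noise=4, seed=0):
    rng = np.random.default_rng(seed)
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    data = {"signal": y + 0.3 * rng.normal(size=n)}
    for i in range(n_noise):
        data[f"noise{i}"] = rng.normal(size=n)
    return pd.DataFrame(data), y


class TestUnivariateAUC:
    def test_label_feature_is_perfect(self):
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        assert univariate_auc(y.astype(float), y) == 1.0
        # orientation correction: anti-correlated feature scores the same
        assert univariate_auc(-y.astype(float), y) == 1.0

    def test_independent_feature_is_chance_level(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 4000)
        x = rng.normal(size=4000)
        assert univariate_auc(x, y) == pytest.approx(0.5, abs=0.03)

    def test_equals_normalized_mann_whitney_u_by_pair_counting(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = np.r_[np.zeros(22), np.ones(18)].astype(int)
        pos, neg = x[y == 1], x[y == 0]
        u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        auc_raw = u / (len(pos) * len(neg))
        assert univariate_auc(x, y) == pytest.approx(max(auc_raw, 1 - auc_raw))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            univariate_auc([1.0, 2.0], [1, 1])


class TestNestedCV:
    def test_outer_folds_partition_the_cohort(self):
        X, y = _signal_dataset()
        res = nested_cv(X, y, SMALL_LR, seed=7)
        seen = np.concatenate([f.test_index for f in res.folds])
        assert len(seen) == len(X)
        assert len(np.unique(seen)) == len(X)
        assert len(res.pooled_scores) == len(X)

    def test_perfectly_separable_cohort_scores_auc_one(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        X = pd.DataFrame({"f": y + 0.01 * rng.normal(size=60),
                          "g": rng.normal(size=60)})
        res = nested_cv(X, y, SMALL_LR, seed=7)
        assert res.auc == 1.0

    def test_transform_fitted_on_training_rows_only(self):
        """Leakage check by recomputation of the per-fold scheme."""
        X, y = _signal_dataset()
        res = nested_cv(X, y, SMALL_LR, seed=7, representation="fuzzy")
        from sklearn.model_selection import StratifiedKFold
        outer = StratifiedKFold(n_splits=N_OUTER_FOLDS, shuffle=True, random_state=7)
        for fold, (tr, te) in zip(res.folds, outer.split(X, y)):
            scheme = fit_scheme(X.iloc[tr])
            assert np.array_equal(fold.test_index, te)
            # scheme depends on training rows only: refit reproduces it
            again = fit_scheme(X.iloc[tr])
            assert scheme.x_min.equals(again.x_min)
            # and is genuinely independent of the test rows
            assert not set(fold.test_index) & set(tr)

    def test_pooled_auc_invariant_to_monotone_score_transform(self):
        X, y = _signal_dataset()
        res = nested_cv(X, y, SMALL_LR, seed=7)
        from sklearn.metrics import roc_auc_score
        warped = np.tanh(3.0 * res.pooled_scores) + 2.0
        assert roc_auc_score(res.pooled_labels, warped) == pytest.approx(res.auc)

    def test_single_class_rejected(self):
        X, _ = _signal_dataset()
        with pytest.raises(ValueError, match="two classes"):
            nested_cv(X, np.zeros(len(X), dtype=int), SMALL_LR)


class TestRFE:
    def test_lone_signal_feature_survives_to_the_end(self):
        X, y = _signal_dataset(n=60, n_noise=3)
        subset = rfe_select(X, y, "LR", 1, params={"C": 1}, seed=0)
        assert subset == ["signal"]

    def test_requesting_all_but_one_runs_one_round(self):
        X, y = _signal_dataset(n=40, n_noise=2)
        subset = rfe_select(X, y, "LR", X.shape[1] - 1, params={"C": 1}, seed=0)
        assert len(subset) == X.shape[1] - 1

    def test_path_orders_every_feature_once(self):
        X, y = _signal_dataset(n=40, n_noise=2)
        order = rfe_path(X, y, "LR", {"C": 1}, seed=0)
        assert len(order) == X.shape[1] - 1
        assert len(set(order)) == len(order)

    def test_out_of_range_n_features_rejected(self):
        X, y = _signal_dataset(n=40, n_noise=2)
        with pytest.raises(ValueError, match="n_features"):
            rfe_select(X, y, "LR", 0)
        with pytest.raises(ValueError, match="n_features"):
            rfe_select(X, y, "LR", X.shape[1])


class TestGroupCompare:
    def test_identical_groups_are_not_significant(self):
        x = np.tile(np.arange(10.0), 2)
        labels = np.r_[np.zeros(10), np.ones(10)].astype(int)
        rep = group_compare(pd.DataFrame({"f": x}), labels)
        assert rep.loc[0, "mannwhitney_p"] > 0.9
        assert not rep.loc[0, "significant"]

    def test_well_separated_groups_are_highly_significant(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 25)
        b = rng.normal(3, 1, 23)
        rep = group_compare(pd.DataFrame({"f": np.r_[a, b]}),
                            np.r_[np.zeros(25), np.ones(23)].astype(int))
        assert rep.loc[0, "mannwhitney_p"] < 0.001
        assert rep.loc[0, "significant"]

    def test_zero_variance_feature_flagged_with_p_one(self):
        labels = np.r_[np.zeros(5), np.ones(5)].astype(int)
        rep = group_compare(pd.DataFrame({"f": np.ones(10)}), labels)
        assert rep.loc[0, "mannwhitney_p"] == 1.0
        assert rep.loc[0, "degenerate"]

    def test_report_layout_lists_feature_and_p(self):
        labels = np.r_[np.zeros(5), np.ones(5)].astype(int)
        df = pd.DataFrame({"Ax_low": np.arange(10.0), "Fr_low": np.arange(10.0)[::-1]})
        rep = group_compare(df, labels)
        assert list(rep["feature"]) == ["Ax_low", "Fr_low"]
        assert {"feature", "mannwhitney_p", "significant"} <= set(rep.columns)


class TestExperimentBookkeeping:
    def test_experiment2_enumerates_180_sub_experiments_per_representation(self):
        for rep in ("normalized", "fuzzy"):
            plan = plan_experiment(2, rep)
            assert len(plan) == 180

    def test_experiment3_yields_90_feature_subset_records_per_analysis(self):
        plan = plan_experiment(3, "normalized")
        for analysis in ANALYSES:
            assert sum(p["analysis"] == analysis for p in plan) == 90

    def test_experiment1_covers_each_feature_once_per_analysis(self):
        plan = plan_experiment(1, "normalized")
        assert len(plan) == 2 * 16

    def test_selection_frequency_denominator_is_algorithms_times_folds(self):
        X, y = _signal_dataset(n=40, n_noise=2)
        res = nested_cv(X, y, SMALL_LR, seed=7, rfe_options=[1, 2])
        freq = selection_frequency({"LR": res}, list(X.columns))
        # one algorithm x 10 folds; every fold selects >= 1 feature
        assert (freq >= 0).all() and (freq <= 100).all()
        assert freq["signal"] == 100.0

    def test_lr_weight_average_covers_all_columns(self):
        X, y = _signal_dataset(n=40, n_noise=2)
        res = nested_cv(X, y, SMALL_LR, seed=7)
        w = lr_weight_average(res)
        assert list(w.index) == list(X.columns)
        assert w.idxmax() == "signal"


def test_analysis_subset_builds_binary_labels(feature_table):
    for analysis, disease in ANALYSES.items():
        sub, y = analysis_subset(feature_table, analysis)
        assert set(np.unique(y)) == {0, 1}
        assert (y == 0).sum() == 25
        assert "group" not in sub.columns
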