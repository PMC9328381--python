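import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mtxresponse.classify import (
    ModelSpec,
    balanced_accuracy,
    detection_at_misclassification,
    nested_cv,
    nonresponder_detection_curve,
    pathway_aggregate,
    roc_auc,
    summarize_importance,
    threshold_prediction,
)
from mtxresponse.data import ConfigError, PipelineError
from mtxresponse.features import FeatureMatrix


def feature_matrix(values, patients=None):
    values = np.asarray(values, dtype=float)
    patients = patients or [f"P{j:03d}" for j in range(values.shape[1])]
    return FeatureMatrix(
        pd.DataFrame(values, index=[f"f{i}" for i in range(values.shape[0])], columns=patients),
        "expr_ratio",
    )


class TestMetrics:
    def test_balanced_accuracy_perfect(self):
        assert balanced_accuracy([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_balanced_accuracy_one_class_prediction(self):
        assert balanced_accuracy([0, 1, 0, 1], [1, 1, 1, 1]) == 0.5

    def test_balanced_accuracy_worked_example(self):
        # TP=30, FN=13 (43 positives); TN=30, FP=12 (42 negatives)
        y_true = [1] * 43 + [0] * 42
        y_pred = [1] * 30 + [0] * 13 + [0] * 30 + [1] * 12
        expected = (30 / 43 + 30 / 42) / 2
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(expected, abs=1e-12)

    def test_balanced_accuracy_requires_both_classes(self):
        with pytest.raises(PipelineError):
            balanced_accuracy([1, 1], [1, 0])

    def test_auc_perfect_and_reversed(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert roc_auc([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1]) == 0.0

    def test_auc_pairwise_example(self):
        # pos scores {0.9, 0.4}, neg scores {0.5, 0.1}: 3 of 4 pairs concordant
        assert roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.5, 0.1]) == 0.75

    def test_auc_ties_half_credit(self):
        # one tied pos/neg pair contributes 1/2; three concordant pairs
        assert roc_auc([0, 1, 1, 0], [0.2, 0.2, 0.9, 0.1]) == 0.875

    def test_auc_constant_scores_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            assert roc_auc([0, 1, 0], [0.3, 0.3, 0.3]) == 0.5

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1)), min_size=4, max_size=40))
    def test_auc_complement_under_score_negation(self, pairs):
        y = [p[0] for p in pairs]
        s = [p[1] for p in pairs]
        if len(set(y)) < 2 or len(set(s)) != len(s):
            return  # needs both classes and tie-free scores
        assert roc_auc(y, s) + roc_auc(y, [-x for x in s]) == pytest.approx(1.0)

    def test_threshold_prediction_sweep(self):
        scores = np.array([0.2, 0.5, 0.8])
        assert threshold_prediction(scores, 0.0).sum() == 3
        assert threshold_prediction(scores, 0.9).sum() == 0
        counts = [threshold_prediction(scores, t).sum() for t in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDetectionCurve:
    def test_perfect_classifier_hits_corner(self):
        labels = pd.Series(["nonresponder"] * 3 + ["good"] * 3)
        scores = [0.9, 0.8, 0.7, 0.2, 0.1, 0.0]
        curve = nonresponder_detection_curve(scores, labels)
        at_zero = curve[curve["good_misclassified_fraction"] == 0]
        assert at_zero["nonresponders_detected_fraction"].max() == 1.0

    def test_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(0)
        labels = pd.Series(rng.permutation(["nonresponder"] * 20 + ["good"] * 20))
        curve = nonresponder_detection_curve(rng.random(40), labels)
        x = curve["good_misclassified_fraction"].to_numpy()
        y = curve["nonresponders_detected_fraction"].to_numpy()
        assert (np.diff(x) >= 0).all() and (np.diff(y) >= 0).all()
        assert (x[0], y[0]) == (0.0, 0.0)
        assert (x[-1], y[-1]) == (1.0, 1.0)

    def test_detection_readout(self):
        labels = pd.Series(["nonresponder"] * 2 + ["good"] * 2)
        curve = nonresponder_detection_curve([0.9, 0.1, 0.5, 0.0], labels)
        assert detection_at_misclassification(curve, 0.0) == 0.5


class TestPathwayAggregate:
    def test_singleton_pathway_passes_through(self):
        fm = feature_matrix([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        agg = pathway_aggregate(fm, {"T1": {"f0"}})
        np.testing.assert_allclose(agg.frame.loc["T1"], [1.0, 2.0, 3.0])

    def test_mean_of_members(self):
        fm = feature_matrix([[1.0, 2.0], [3.0, 4.0], [10.0, 10.0]])
        agg = pathway_aggregate(fm, {"T1": {"f0", "f1"}, "T2": {"f2"}, "empty": {"zzz"}})
        np.testing.assert_allclose(agg.frame.loc["T1"], [2.0, 3.0])
        assert set(agg.feature_ids) == {"T1", "T2"}

    def test_no_surviving_pathway_rejected(self):
        fm = feature_matrix([[1.0, 2.0]])
        with pytest.raises(PipelineError):
            pathway_aggregate(fm, {"T1": {"absent"}})

    def test_planted_signal_concentrates_in_its_pathway(self, small_cohort):
        from mtxresponse.data import align_paired_design
        from mtxresponse.features import delta_expression, expression_features, fit_standardizer, apply_standardizer

        c = small_cohort
        pairing = align_paired_design(c.expr_pre, c.expr_wk4, c.samples)
        feats = expression_features(delta_expression(c.expr_pre, c.expr_wk4, pairing))
        std = fit_standardizer(feats, feats.patient_ids)
        z = apply_standardizer(std, feats)
        signal = set(c.ground_truth.signal_genes)
        background = [g for g in feats.feature_ids if g not in signal][:100]
        pathways = {"signal": signal}
        pathways.update({f"bg{i}": set(background[i * 20:(i + 1) * 20]) for i in range(5)})
        agg = pathway_aggregate(z, pathways)
        labels = c.samples.response_by_patient().loc[agg.patient_ids]
        diffs = (agg.frame.loc[:, (labels == "nonresponder").values].mean(axis=1)
                 - agg.frame.loc[:, (labels == "good").values].mean(axis=1)).abs()
        assert diffs.idxmax() == "signal"


class TestSummarizeImportance:
    def test_mean_and_sample_sd(self):
        folds = [pd.Series({"f0": 1.0, "f1": 0.0}), pd.Series({"f0": 3.0, "f1": 0.0})]
        out = summarize_importance(folds)
        assert out.loc["f0", "mean"] == 2.0
        assert out.loc["f0", "sd"] == pytest.approx(np.sqrt(2.0))
        assert out.index[0] == "f0"  # ordered by |mean|

    def test_identical_folds_zero_sd(self):
        folds = [pd.Series({"f0": 1.5})] * 3
        assert summarize_importance(folds).loc["f0", "sd"] == 0.0


class TestNestedCV:
    def _labels(self, patients, n_pos):
        labels = ["nonresponder"] * n_pos + ["good"] * (len(patients) - n_pos)
        return pd.Series(labels, index=patients)

    def test_separable_feature_gives_auc_one(self):
        rng = np.random.default_rng(0)
        n = 40
        sep = np.concatenate([np.ones(20) * 5, -np.ones(20) * 5]) + rng.normal(0, 0.1, n)
        noise = rng.normal(0, 1, (4, n))
        fm = feature_matrix(np.vstack([sep, noise]))
        labels = self._labels(fm.patient_ids, 20)
        result = nested_cv(fm, labels, ModelSpec("l2_logistic"), k_outer=5, k_inner=3, seed=1)
        assert result.summary["roc_auc_mean"] == 1.0
        assert result.summary["roc_auc_sem"] == 0.0

    def test_outer_folds_partition_patients(self):
        rng = np.random.default_rng(1)
        fm = feature_matrix(rng.normal(0, 1, (5, 30)))
        labels = self._labels(fm.patient_ids, 15)
        result = nested_cv(fm, labels, ModelSpec("l2_logistic"), k_outer=5, k_inner=3, seed=2)
        test_sets = [set(a["test_patients"]) for a in result.fold_artifacts]
        assert set().union(*test_sets) == set(fm.patient_ids)
        assert sum(len(s) for s in test_sets) == 30  # pairwise disjoint
        assert not result.scores.isna().any()

    def test_sem_is_sd_over_sqrt_folds(self):
        rng = np.random.default_rng(2)
        fm = feature_matrix(rng.normal(0, 1, (5, 40)))
        labels = self._labels(fm.patient_ids, 20)
        result = nested_cv(fm, labels, ModelSpec("l2_logistic"), k_outer=4, k_inner=3, seed=3)
        folds = result.fold_metrics["roc_auc"].to_numpy()
        assert result.summary["roc_auc_sem"] == pytest.approx(folds.std(ddof=1) / 2.0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        fm = feature_matrix(rng.normal(0, 1, (8, 30)))
        labels = self._labels(fm.patient_ids, 15)
        a = nested_cv(fm, labels, ModelSpec("l2_logistic"), k_outer=3, k_inner=3, seed=7)
        b = nested_cv(fm, labels, ModelSpec("l2_logistic"), k_outer=3, k_inner=3, seed=7)
        assert a.training_checksums() == b.training_checksums()
        pd.testing.assert_series_equal(a.scores, b.scores)

    def test_small_class_raises_stratification_error(self):
        rng = np.random.default_rng(4)
        fm = feature_matrix(rng.normal(0, 1, (3, 16)))
        labels = self._labels(fm.patient_ids, 8)
        with pytest.raises(PipelineError, match="stratification"):
            nested_cv(fm, labels, ModelSpec("l2_logistic"), k_outer=10, seed=0)

    def test_random_forest_family_runs(self):
        rng = np.random.default_rng(5)
        fm = feature_matrix(rng.normal(0, 1, (6, 24)))
        labels = self._labels(fm.patient_ids, 12)
        spec = ModelSpec("random_forest", hyperparameter_grid=[{"n_estimators": 30, "max_depth": 4}])
        result = nested_cv(fm, labels, spec, k_outer=3, k_inner=2, seed=6)
        assert result.coefficient_summary is None
        assert len(result.fold_metrics) == 3

    def test_pathway_family_produces_pathway_coefficients(self):
        rng = np.random.default_rng(6)
        fm = feature_matrix(rng.normal(0, 1, (10, 24)))
        labels = self._labels(fm.patient_ids, 12)
        pathways = {"A": {"f0", "f1", "f2"}, "B": {"f5", "f6"}}
        spec = ModelSpec("pathway_supported", pathways=pathways)
        result = nested_cv(fm, labels, spec, k_outer=3, k_inner=2, seed=8)
        assert set(result.coefficient_summary.index) == {"A", "B"}

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError):
            ModelSpec("gradient_boosting")
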