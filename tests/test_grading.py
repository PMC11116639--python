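"""AHI arithmetic, severity bins, and evaluation-metric formulas."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import f1_score, precision_score, recall_score, roc_auc_score

from snoregrade.classify import train_event_classifier
from snoregrade.exceptions import ValidationError
from snoregrade.grading import (
    binary_metrics,
    compute_ahi,
    count_events,
    feature_importance,
    grade_severity,
    regression_metrics,
    roc_auc,
)


class TestCountEvents:
    def test_mode_contrast_on_mixed_record(self):
        record = np.array([0, 1, 1, 0, 1])
        assert count_events(record, "positive_minutes") == 3
        assert count_events(record, "contiguous_runs") == 2

    def test_all_zeros(self):
        assert count_events(np.zeros(480, int), "positive_minutes") == 0
        assert count_events(np.zeros(480, int), "contiguous_runs") == 0

    def test_all_ones_mode_contrast(self):
        assert count_events(np.ones(480, int), "positive_minutes") == 480
        assert count_events(np.ones(480, int), "contiguous_runs") == 1

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            count_events(np.array([0, 2, 1]))


class TestAhi:
    @pytest.mark.parametrize(
        "n,hours,expected", [(16, 8, 2.0), (44, 8, 5.5), (389, 8, 48.625)]
    )
    def test_exact_division(self, n, hours, expected):
        assert compute_ahi(n, hours).ahi == expected

    def test_nonpositive_hours_rejected(self):
        with pytest.raises(ValidationError):
            compute_ahi(10, 0)


class TestSeverity:
    @pytest.mark.parametrize(
        "ahi,label",
        [
            (0.0, 0), (4.999, 0), (5.0, 1), (5.5, 1), (11.875, 1), (14.999, 1),
            (15.0, 2), (18.0, 2), (29.999, 2), (30.0, 3), (48.625, 3),
        ],
    )
    def test_bin_edges_and_examples(self, ahi, label):
        severity = grade_severity(ahi)
        assert severity.label == label
        assert severity.name == ("normal", "mild", "moderate", "severe")[label]

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            grade_severity(-0.1)

    @given(st.integers(0, 480))
    def test_monotone_in_event_count_at_fixed_duration(self, n):
        a = grade_severity(compute_ahi(n, 8.0).ahi).label
        b = grade_severity(compute_ahi(n + 1, 8.0).ahi).label
        assert b >= a


class TestBinaryMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1, 1])
        report = binary_metrics(y, y)
        assert (
            report.precision, report.recall, report.f1,
            report.accuracy, report.specificity,
        ) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_balanced_2x2_table(self):
        y_true = np.array([1, 1, 0, 0])
        y_pred = np.array([1, 0, 1, 0])
        report = binary_metrics(y_true, y_pred)
        assert (report.tp, report.fp, report.fn, report.tn) == (1, 1, 1, 1)
        assert report.precision == report.recall == report.f1 == report.accuracy == 0.5
        assert report.n == 4

    def test_no_predicted_positives_sentinel(self):
        with pytest.warns(UserWarning, match="precision"):
            report = binary_metrics(np.array([1, 1, 0]), np.zeros(3, int))
        assert report.precision == 0.0 and report.recall == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            binary_metrics(np.array([0, 1]), np.array([0, 1, 1]))

    @given(st.integers(0, 5000))
    def test_matches_sklearn_on_random_tables(self, seed):
        gen = np.random.default_rng(seed)
        y_true = gen.integers(0, 2, 40)
        y_pred = gen.integers(0, 2, 40)
        if y_true.sum() in (0, len(y_true)):
            y_true[0] = 1 - y_true[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = binary_metrics(y_true, y_pred)
        assert report.precision == pytest.approx(
            precision_score(y_true, y_pred, zero_division=0)
        )
        assert report.recall == pytest.approx(
            recall_score(y_true, y_pred, zero_division=0)
        )
        assert report.f1 == pytest.approx(f1_score(y_true, y_pred, zero_division=0))
        assert report.n == 40


class TestRegressionMetrics:
    def test_perfect_fit(self):
        assert regression_metrics([1, 2, 3], [1, 2, 3]) == (0.0, 0.0, 1.0)

    def test_hand_computed_case(self):
        mae, mse, r2 = regression_metrics([0.0, 2.0], [1.0, 1.0])
        assert (mae, mse, r2) == (1.0, 1.0, 0.0)

    def test_constant_prediction_at_mean_scores_zero(self):
        _, _, r2 = regression_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert r2 == 0.0

    def test_literal_denominator(self):
        # y=(0,2,4), yhat=(1,1,1): ss_res=11; alternative denominator
        # sum((ybar - yhat)^2) = 3, standard denominator = 8
        mae, mse, r2_std = regression_metrics([0.0, 2.0, 4.0], [1.0, 1.0, 1.0])
        assert (mae, mse) == (5 / 3, 11 / 3)
        assert r2_std == pytest.approx(1 - 11 / 8)
        _, _, r2_pf = regression_metrics(
            [0.0, 2.0, 4.0], [1.0, 1.0, 1.0], r2_mode="literal"
        )
        assert r2_pf == pytest.approx(1 - 11 / 3)

    def test_zero_variance_sentinel(self):
        with pytest.warns(UserWarning):
            _, _, r2 = regression_metrics([1.0, 1.0], [0.0, 2.0])
        assert r2 == 0.0


def pairs_auc(y_true, scores):
    """All-pairs rank oracle: P(score+ > score-), ties counted half."""
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, points = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0
        assert np.all(np.diff(points["fpr"]) >= 0)
        assert np.all(np.diff(points["tpr"]) >= 0)

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0, 1, 0, 1], np.full(4, 0.5))
        assert auc == 0.5

    @given(st.integers(0, 5000))
    def test_matches_all_pairs_oracle_and_sklearn(self, seed):
        gen = np.random.default_rng(seed)
        n = int(gen.integers(5, 200))
        y = gen.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        scores = np.round(gen.uniform(size=n), 2)  # rounding forces ties
        auc, _ = roc_auc(y, scores)
        assert auc == pytest.approx(pairs_auc(y, scores), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])


class TestFeatureImportance:
    def _model_with_noise_column(self):
        gen = np.random.default_rng(6)
        n = 300
        y = gen.integers(0, 2, n)
        features = pd.DataFrame(
            {
                "informative": y + 0.3 * gen.normal(size=n),
                "noise": gen.normal(size=n),
            }
        )
        return train_event_classifier(features, y), features, y

    def test_noise_column_ranks_below_informative(self):
        model, features, y = self._model_with_noise_column()
        table = feature_importance(model, features, y, n_repeats=5, seed=0)
        assert table.iloc[0]["feature"] == "informative"
        assert table.iloc[0]["auc_drop_mean"] > table.iloc[-1]["auc_drop_mean"]

    def test_seeded_repeats_identical(self):
        model, features, y = self._model_with_noise_column()
        a = feature_importance(model, features, y, n_repeats=3, seed=9)
        b = feature_importance(model, features, y, n_repeats=3, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_duplicated_informative_column_shares_importance(self):
        gen = np.random.default_rng(10)
        n = 300
        y = gen.integers(0, 2, n)
        base = y + 0.3 * gen.normal(size=n)
        features = pd.DataFrame(
            {"a": base, "a_copy": base, "noise": gen.normal(size=n)}
        )
        model = train_event_classifier(features, y)
        table = feature_importance(model, features, y, n_repeats=10, seed=1)
        drops = table.set_index("feature")["auc_drop_mean"]
        assert drops["a"] >= 0.0 and drops["a_copy"] >= 0.0

    def test_invalid_inputs_rejected(self):
        model, features, y = self._model_with_noise_column()
        with pytest.raises(ValidationError):
            feature_importance(model, features, y, n_repeats=0)
        with pytest.raises(ValidationError):
            feature_importance("not a model", features, y)
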