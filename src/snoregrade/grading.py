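"""AHI computation, four-class OSAHS severity grading and evaluation metrics.

The Apnea-Hypopnea Index is ``AHI = N / t`` with N the overnight event
count and t the sleep duration in hours.  Severity bins::

    0  normal / simple snoring   AHI < 5
    1  mild                      5 <= AHI < 15
    2  moderate                  15 <= AHI < 30
    3  severe                    AHI >= 30

Two event-counting conventions are offered.  ``positive_minutes``
(default) counts positive minutes of the per-minute record — consistent
with a per-minute classifier whose AHI estimates over an 8-h night are
fractions with denominator 8.  ``contiguous_runs`` counts maximal runs
of consecutive positive minutes, the clinically conventional notion of
"an event".

Binary metrics follow the standard 2x2 definitions (precision
TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean, specificity
TN/(TN+FP)); when a denominator is 0 the metric is reported as 0.0 with
a warning rather than NaN.  ROC/AUC is a threshold sweep with
trapezoidal integration, equal to the all-pairs rank statistic with ties
counted half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "SEVERITY_NAMES",
    "SEVERITY_THRESHOLDS",
    "AhiResult",
    "SeverityLabel",
    "EvalReport",
    "count_events",
    "compute_ahi",
    "grade_severity",
    "binary_metrics",
    "regression_metrics",
    "roc_auc",
    "feature_importance",
]

SEVERITY_NAMES = ("normal", "mild", "moderate", "severe")
#: lower AHI edges of the mild / moderate / severe bins (events per hour)
SEVERITY_THRESHOLDS = (5.0, 15.0, 30.0)

COUNTING_MODES = ("positive_minutes", "contiguous_runs")


@dataclass(frozen=True)
class AhiResult:
    """Overnight event count, sleep duration and their ratio."""

    n_events: int
    sleep_hours: float
    ahi: float
    counting_mode: str = "positive_minutes"


@dataclass(frozen=True)
class SeverityLabel:
    label: int
    name: str


def _as_binary(values, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{what} must contain only 0/1 values")
    return arr.astype(int)


def count_events(record, mode: str = "positive_minutes") -> int:
    """Count overnight events from a binary per-minute record."""
    if mode not in COUNTING_MODES:
        raise ValidationError(f"unknown counting mode {mode!r}; choose from {COUNTING_MODES}")
    labels = _as_binary(
        record.labels if hasattr(record, "labels") else record, "event record"
    )
    if mode == "positive_minutes":
        return int(labels.sum())
    padded = np.concatenate([[0], labels])
    return int((np.diff(padded) == 1).sum())


def compute_ahi(
    n_events: int, sleep_hours: float, counting_mode: str = "positive_minutes"
) -> AhiResult:
    """AHI = N / t (events per hour of sleep), exact division."""
    if sleep_hours <= 0:
        raise ValidationError(f"sleep_hours must be > 0, got {sleep_hours}")
    if n_events < 0:
        raise ValidationError(f"n_events must be >= 0, got {n_events}")
    return AhiResult(
        n_events=int(n_events),
        sleep_hours=float(sleep_hours),
        ahi=n_events / sleep_hours,
        counting_mode=counting_mode,
    )


def grade_severity(ahi: float) -> SeverityLabel:
    """Map an AHI value to the four-class severity label (0-3)."""
    if ahi < 0:
        raise ValidationError(f"AHI must be >= 0, got {ahi}")
    label = int(np.digitize(ahi, SEVERITY_THRESHOLDS))
    return SeverityLabel(label=label, name=SEVERITY_NAMES[label])


@dataclass
class EvalReport:
    """Counts and derived metrics for a binary prediction task."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _safe_ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} denominator is 0; reporting 0.0", UserWarning, stacklevel=3)
        return 0.0
    return num / den


def binary_metrics(y_true, y_pred) -> EvalReport:
    """2x2 confusion counts and the derived metrics."""
    y_true = _as_binary(y_true, "y_true")
    y_pred = _as_binary(y_pred, "y_pred")
    if len(y_true) != len(y_pred):
        raise ValidationError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    precision = _safe_ratio(tp, tp + fp, "precision")
    recall = _safe_ratio(tp, tp + fn, "recall")
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=(tp + tn) / len(y_true) if len(y_true) else 0.0,
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
    )


def regression_metrics(
    y_true, y_pred, r2_mode: str = "standard"
) -> tuple[float, float, float]:
    """MAE, MSE and R².

    ``r2_mode="standard"``: ``1 - sum (y - yhat)^2 / sum (y - ybar)^2``.
    ``r2_mode="literal"``: denominator ``sum (ybar - yhat)^2``,
    an alternative convention that normalizes by the spread of the
    predictions around the true mean instead.
    Zero variance in ``y_true`` under the standard form yields 0.0 with
    a warning.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValidationError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    residual = y_true - y_pred
    mae = float(np.mean(np.abs(residual)))
    mse = float(np.mean(residual**2))
    ss_res = float(np.sum(residual**2))
    if r2_mode == "literal":
        denom = float(np.sum((y_true.mean() - y_pred) ** 2))
    elif r2_mode == "standard":
        denom = float(np.sum((y_true - y_true.mean()) ** 2))
    else:
        raise ValidationError(f"unknown r2_mode {r2_mode!r}")
    if denom == 0:
        warnings.warn("R² denominator is 0; reporting 0.0", UserWarning, stacklevel=2)
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / denom
    return mae, mse, r2


def roc_auc(y_true, scores) -> tuple[float, pd.DataFrame]:
    """ROC curve by threshold sweep and trapezoidal AUC.

    Equals the rank statistic: the probability that a random positive
    outscores a random negative, ties counted one half.  Requires both
    classes present.
    """
    y_true = _as_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=np.float64)
    if len(y_true) != len(scores):
        raise ValidationError(f"length mismatch: {len(y_true)} vs {len(scores)}")
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes in y_true")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tps = np.cumsum(y_true[order])
    fps = np.cumsum(1 - y_true[order])
    # keep the last index of each tied-score block, prepend the origin
    distinct = np.flatnonzero(np.diff(sorted_scores, append=-np.inf))
    tpr = np.concatenate([[0.0], tps[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fps[distinct] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return auc, points


def feature_importance(
    model,
    features: pd.DataFrame,
    labels,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance: mean AUC drop when one column is shuffled.

    ``model`` is a :class:`~snoregrade.classify.TrainedEventModel`.
    Returns a table (feature, auc_drop_mean, auc_drop_std) sorted by
    descending mean drop; seeded, so repeated calls agree.
    """
    from .classify import TrainedEventModel, predict_minutes  # cycle guard

    if not isinstance(model, TrainedEventModel):
        raise ValidationError("feature_importance needs a TrainedEventModel")
    if n_repeats < 1:
        raise ValidationError(f"n_repeats must be >= 1, got {n_repeats}")
    y = np.asarray(labels.labels if hasattr(labels, "labels") else labels)
    baseline, _ = roc_auc(y, predict_minutes(model, features)["score"].to_numpy())
    rng = np.random.default_rng(seed)
    records = []
    for column in features.columns:
        drops = []
        for _ in range(n_repeats):
            shuffled = features.copy()
            shuffled[column] = rng.permutation(shuffled[column].to_numpy())
            auc, _ = roc_auc(y, predict_minutes(model, shuffled)["score"].to_numpy())
            drops.append(baseline - auc)
        records.append(
            {
                "feature": column,
                "auc_drop_mean": float(np.mean(drops)),
                "auc_drop_std": float(np.std(drops)),
            }
        )
    table = pd.DataFrame(records).sort_values(
        "auc_drop_mean", ascending=False, ignore_index=True
    )
    return table
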