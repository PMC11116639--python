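"""Feature fusion and the per-minute boosted-tree apnea-event classifier.

Per minute t the fused feature is the concatenation of the semantic
vector s_t and the acoustic vector C_t.  A ``literal`` fusion mode
additionally concatenates the event record e_t itself; since e_t is the
prediction target, feeding it in leaks the label, so the default
``inference_safe`` mode excludes it and the literal mode exists only to
demonstrate the leakage.

The classifier is gradient-boosted trees (XGBoost) minimizing the
regularized objective ``sum_i l(y_i, yhat_i) + sum_k Omega(f_k)`` with
binary logistic loss.  Default hyperparameters are values tuned for
this task by cross-validation: learning_rate 0.3, max_depth 9,
subsample 0.6, reg_lambda 10, reg_alpha 0.1, colsample_bytree 0.5,
gamma 0.2; 100 boosting rounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold
from xgboost import XGBClassifier

from .exceptions import ConfigError, DimensionError, ValidationError
from .labeling import EventRecord

__all__ = [
    "FUSION_MODES",
    "ClassifierConfig",
    "TrainedEventModel",
    "fuse",
    "train_event_classifier",
    "predict_minutes",
    "cross_validate",
    "save_model",
    "load_model",
]

FUSION_MODES = ("inference_safe", "literal")
EVENT_COLUMN = "event"


def fuse(
    semantic_matrix: pd.DataFrame,
    mfcc_matrix: pd.DataFrame,
    event_record: EventRecord | None = None,
    mode: str = "inference_safe",
) -> pd.DataFrame:
    """Concatenate per-minute features column-wise, order (s, C[, e]).

    ``inference_safe`` (default) yields T x (d_s + L); ``literal``
    appends the event record as a trailing column, which leaks the
    label into the features and exists only for demonstration.
    """
    if mode not in FUSION_MODES:
        raise ConfigError(f"unknown fusion mode {mode!r}; choose from {FUSION_MODES}")
    if len(semantic_matrix) != len(mfcc_matrix):
        raise DimensionError(
            f"semantic matrix has {len(semantic_matrix)} minutes but MFCC "
            f"matrix has {len(mfcc_matrix)}"
        )
    parts = [
        semantic_matrix.reset_index(drop=True),
        mfcc_matrix.reset_index(drop=True),
    ]
    if mode == "literal":
        if event_record is None:
            raise ValidationError("literal fusion requires an event record")
        if event_record.n_minutes != len(mfcc_matrix):
            raise DimensionError(
                f"event record has {event_record.n_minutes} minutes but MFCC "
                f"matrix has {len(mfcc_matrix)}"
            )
        warnings.warn(
            "literal fusion feeds the event label into the feature "
            "matrix; use it only to demonstrate label leakage",
            UserWarning,
            stacklevel=2,
        )
        parts.append(
            pd.DataFrame({EVENT_COLUMN: event_record.labels.astype(np.float64)})
        )
    fused = pd.concat(parts, axis=1)
    fused.index = mfcc_matrix.index
    return fused


@dataclass(frozen=True)
class ClassifierConfig:
    """Boosted-tree hyperparameters (defaults tuned by cross-validation)."""

    learning_rate: float = 0.3
    max_depth: int = 9
    subsample: float = 0.6
    reg_lambda: float = 10.0
    reg_alpha: float = 0.1
    colsample_bytree: float = 0.5
    gamma: float = 0.2
    n_rounds: int = 100
    objective: str = "binary:logistic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ConfigError(f"learning_rate must be in (0, 1], got {self.learning_rate}")
        if self.max_depth < 1 or self.n_rounds < 1:
            raise ConfigError("max_depth and n_rounds must be >= 1")
        for name in ("subsample", "colsample_bytree"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        for name in ("reg_lambda", "reg_alpha", "gamma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def to_xgboost_params(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "max_depth": self.max_depth,
            "subsample": self.subsample,
            "reg_lambda": self.reg_lambda,
            "reg_alpha": self.reg_alpha,
            "colsample_bytree": self.colsample_bytree,
            "gamma": self.gamma,
            "n_estimators": self.n_rounds,
            "objective": self.objective,
            "random_state": self.seed,
            "n_jobs": 1,
            "tree_method": "hist",
            "eval_metric": "logloss",
        }


@dataclass
class TrainedEventModel:
    """A fitted per-minute event classifier plus provenance."""

    booster: XGBClassifier
    config: ClassifierConfig
    feature_names: list[str]
    train_fingerprint: str
    training_loss: list[float] = field(default_factory=list)


def _check_features(features: pd.DataFrame) -> np.ndarray:
    values = features.to_numpy(dtype=np.float64)
    if not np.isfinite(values).all():
        bad = [
            c for c, ok in zip(features.columns, np.isfinite(values).all(axis=0)) if not ok
        ]
        raise ValidationError(f"non-finite values in feature columns {bad}")
    return values


def train_event_classifier(
    features: pd.DataFrame, labels, config: ClassifierConfig | None = None
) -> TrainedEventModel:
    """Fit the boosted-tree minute classifier; seeded and reproducible.

    ``labels`` may be an :class:`EventRecord` or any binary array with one
    entry per feature row.  The per-round training log-loss is recorded.
    """
    config = config or ClassifierConfig()
    y = labels.labels if isinstance(labels, EventRecord) else np.asarray(labels)
    if len(y) != len(features):
        raise DimensionError(
            f"{len(features)} feature rows but {len(y)} labels"
        )
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")
    X = _check_features(features)
    model = XGBClassifier(**config.to_xgboost_params())
    model.fit(X, y, eval_set=[(X, y)], verbose=False)
    loss = model.evals_result()["validation_0"]["logloss"]
    fingerprint = f"n={len(y)} positives={int(y.sum())} d={X.shape[1]}"
    return TrainedEventModel(
        booster=model,
        config=config,
        feature_names=list(features.columns),
        train_fingerprint=fingerprint,
        training_loss=[float(v) for v in loss],
    )


def predict_minutes(
    model: TrainedEventModel, features: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-minute event scores in [0, 1] and hard labels at the threshold."""
    if list(features.columns) != model.feature_names:
        raise ValidationError(
            f"feature columns {list(features.columns)} do not match the "
            f"training columns {model.feature_names}"
        )
    X = _check_features(features)
    scores = model.booster.predict_proba(X)[:, 1]
    return pd.DataFrame(
        {"score": scores, "label": (scores >= threshold).astype(int)},
        index=features.index,
    )


def cross_validate(
    features: pd.DataFrame,
    labels,
    groups,
    grid: list[ClassifierConfig],
    k: int = 5,
) -> tuple[ClassifierConfig, pd.DataFrame]:
    """Grouped k-fold hyperparameter search by mean validation AUC.

    Folds are grouped (all minutes of one night stay together) to avoid
    within-night leakage.  Returns the best config and the full per-fold
    result table.
    """
    from .grading import roc_auc  # local import to avoid a cycle

    y = labels.labels if isinstance(labels, EventRecord) else np.asarray(labels)
    groups = np.asarray(groups)
    if k < 2:
        raise ConfigError(f"k must be >= 2, got {k}")
    if len(np.unique(groups)) < k:
        raise ValidationError(
            f"only {len(np.unique(groups))} nights for {k} folds"
        )
    if not grid:
        raise ConfigError("empty hyperparameter grid")
    X = _check_features(features)
    records = []
    for ci, config in enumerate(grid):
        splitter = GroupKFold(n_splits=k)
        for fold, (tr, va) in enumerate(splitter.split(X, y, groups)):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                continue  # degenerate fold: AUC undefined
            model = XGBClassifier(**config.to_xgboost_params())
            model.fit(X[tr], y[tr], verbose=False)
            scores = model.predict_proba(X[va])[:, 1]
            auc, _ = roc_auc(y[va], scores)
            acc = float(((scores >= 0.5).astype(int) == y[va]).mean())
            records.append(
                {"config_index": ci, "fold": fold, "auc": auc, "accuracy": acc}
            )
    results = pd.DataFrame(records)
    if results.empty:
        raise ValidationError("every fold was single-class; cannot cross-validate")
    mean_auc = results.groupby("config_index")["auc"].mean()
    best = grid[int(mean_auc.idxmax())]
    return best, results


def save_model(model: TrainedEventModel, path: str) -> None:
    """Serialize a trained model (booster + config + feature names) to one file."""
    joblib.dump(
        {
            "booster": model.booster,
            "config": asdict(model.config),
            "feature_names": model.feature_names,
            "train_fingerprint": model.train_fingerprint,
            "training_loss": model.training_loss,
        },
        path,
    )


def load_model(path: str) -> TrainedEventModel:
    payload = joblib.load(path)
    return TrainedEventModel(
        booster=payload["booster"],
        config=ClassifierConfig(**payload["config"]),
        feature_names=payload["feature_names"],
        train_fingerprint=payload["train_fingerprint"],
        training_loss=payload["training_loss"],
    )
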