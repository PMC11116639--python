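"""End-to-end orchestration: audio -> features -> classifier -> severity.

The canonical run takes a cohort of nights (audio plus annotated apnea
events), extracts per-minute MFCC features, optionally references them
against each night's own snore baseline (see
:func:`~snoregrade.features.calibrate_to_night`), standardizes them with
statistics fitted on training nights only, encodes each minute's
sentence through the configured text encoder, fuses semantic and
acoustic features, trains the per-minute event classifier on the
training nights, predicts held-out nights, and grades each held-out
night's severity from its estimated AHI.

Two evaluation drivers exist.  :func:`run_pipeline` performs one seeded
night-level 80/20 split.  :func:`cross_fit_pipeline` deals the nights
into folds and grades every night while it is held out, which gives a
cohort-sized sample for severity accuracy and for the correlation
between ground-truth and estimated AHI — a two- or three-night test set
cannot support either statistic.

A night's *reference* severity is graded from its ground-truth minute
record under the same event-counting convention used for predictions, so
severity accuracy isolates classifier error rather than the systematic
offset between placed-event counts and labeled-minute counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .classify import TrainedEventModel, fuse, predict_minutes, train_event_classifier
from .config import RunConfig
from .encoding import DeterministicEncoder, encode_night
from .exceptions import ConfigError, ValidationError
from .features import (
    FrameSpec,
    calibrate_to_night,
    minute_loudness,
    minute_mfcc,
    standardize_features,
)
from .grading import binary_metrics, compute_ahi, count_events, grade_severity, roc_auc
from .io import AudioRecording
from .labeling import EventRecord
from .simulate import SyntheticNight

__all__ = [
    "NightInput",
    "PipelineResult",
    "split_nights",
    "run_pipeline",
    "cross_fit_pipeline",
    "grade_night_record",
]


@dataclass
class NightInput:
    """One night of input data, by id."""

    night_id: str
    audio: AudioRecording
    truth_record: EventRecord

    @classmethod
    def from_synthetic(cls, night: SyntheticNight, night_id: str) -> "NightInput":
        return cls(night_id=night_id, audio=night.audio, truth_record=night.truth_record)


@dataclass
class PipelineResult:
    """Outputs of one end-to-end run."""

    severity_table: pd.DataFrame  # one row per graded held-out night
    minute_metrics: object  # EvalReport over pooled held-out minutes
    minute_auc: float
    severity_accuracy: float
    ahi_rank_correlation: float
    model: TrainedEventModel  # the (last) fitted model
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)


def make_encoder(config: RunConfig):
    if config.encoder_backend == "deterministic_fallback":
        return DeterministicEncoder(d_s=config.encoder_dim, seed=config.random_seed)
    if config.encoder_backend == "pretrained_biomedical_lm":
        raise ConfigError(
            "pretrained backend needs a model directory; construct "
            "PretrainedBiomedicalEncoder directly and pass it to run_pipeline"
        )
    raise ConfigError(f"unknown encoder backend {config.encoder_backend!r}")


def grade_night_record(record: EventRecord, config: RunConfig):
    """Severity label implied by a per-minute record under the run's
    counting convention."""
    hours = record.n_minutes / 60.0
    n = count_events(record, mode=config.counting_mode)
    return grade_severity(compute_ahi(n, hours, config.counting_mode).ahi)


def split_nights(
    nights: list[NightInput], config: RunConfig
) -> tuple[list[NightInput], list[NightInput]]:
    """Seeded night-level 80/20 split, optionally stratified by the
    reference severity class so the test set spans severities."""
    if len(nights) < 2:
        raise ValidationError("need at least 2 nights to split")
    n_test = max(1, int(round(config.test_fraction * len(nights))))
    folds = _stratified_folds(nights, config, n_folds=None, n_test=n_test)
    test_idx = set(folds[0])
    train = [n for i, n in enumerate(nights) if i not in test_idx]
    test = [n for i, n in enumerate(nights) if i in test_idx]
    return train, test


def _stratified_folds(
    nights: list[NightInput],
    config: RunConfig,
    n_folds: int | None,
    n_test: int | None = None,
) -> list[list[int]]:
    """Deal night indices into folds, round-robin across severity classes.

    With ``n_folds=None`` a single test fold of ``n_test`` nights is
    produced (the 80/20 split); otherwise every night lands in exactly
    one of ``n_folds`` folds.
    """
    rng = np.random.default_rng(config.random_seed)
    order = np.asarray(range(len(nights)))
    if config.stratify_split:
        classes = np.array(
            [grade_night_record(n.truth_record, config).label for n in nights]
        )
        # shuffle within class, then interleave classes
        interleaved: list[int] = []
        pools = {
            c: list(rng.permutation(np.flatnonzero(classes == c)))
            for c in np.unique(classes)
        }
        while any(pools.values()):
            for c in sorted(pools):
                if pools[c]:
                    interleaved.append(int(pools[c].pop()))
        order = np.asarray(interleaved)
    else:
        order = rng.permutation(order)
    if n_folds is None:
        return [list(order[:n_test])]
    return [list(order[f::n_folds]) for f in range(n_folds)]


def _night_features(night: NightInput, config: RunConfig) -> pd.DataFrame:
    spec = FrameSpec.from_seconds(
        config.frame_length_s, config.hop_length_s, night.audio.sample_rate,
        config.window_name,
    )
    matrix = minute_mfcc(
        night.audio,
        frame_spec=spec,
        n_fft=config.n_fft,
        n_mel_filters=config.n_mel_filters,
        n_mfcc=config.n_mfcc,
        fmin_hz=config.fmin_hz,
        fmax_hz=config.fmax_hz,
        aggregation=config.minute_aggregation,
    )
    if config.night_calibration:
        matrix = calibrate_to_night(
            matrix, minute_loudness(night.audio), config.calibration_anchor_minutes
        )
    return matrix


def _fit_and_grade(
    train: list[NightInput],
    test: list[NightInput],
    mfcc: dict[str, pd.DataFrame],
    config: RunConfig,
    encoder,
):
    """Standardize on train nights, fit, grade the test nights."""
    train_rows = pd.concat([mfcc[n.night_id] for n in train], ignore_index=True)
    scaler, _ = standardize_features(train_rows)

    def fused_features(night: NightInput) -> pd.DataFrame:
        raw = mfcc[night.night_id]
        std = pd.DataFrame(
            scaler.transform(raw.to_numpy(dtype=np.float64)),
            index=raw.index, columns=raw.columns,
        )
        semantic = encode_night(std, encoder, precision=config.sentence_precision)
        return fuse(semantic, std, night.truth_record, mode=config.fusion_mode)

    X_train = pd.concat([fused_features(n) for n in train], ignore_index=True)
    y_train = np.concatenate([n.truth_record.labels for n in train])
    model = train_event_classifier(X_train, y_train, config.classifier)

    rows, y_true_all, scores_all = [], [], []
    for night in test:
        features = fused_features(night)
        pred = predict_minutes(model, features, threshold=config.decision_threshold)
        hours = night.truth_record.n_minutes / 60.0
        est = compute_ahi(
            count_events(pred["label"].to_numpy(), config.counting_mode),
            hours, config.counting_mode,
        )
        ref = compute_ahi(
            count_events(night.truth_record, config.counting_mode),
            hours, config.counting_mode,
        )
        rows.append(
            {
                "night_id": night.night_id,
                "sleep_hours": hours,
                "ahi_reference": ref.ahi,
                "ahi_estimated": est.ahi,
                "label_reference": grade_severity(ref.ahi).label,
                "label_estimated": grade_severity(est.ahi).label,
            }
        )
        y_true_all.append(night.truth_record.labels)
        scores_all.append(pred["score"].to_numpy())
    return model, rows, np.concatenate(y_true_all), np.concatenate(scores_all)


def _summarize(
    severity: pd.DataFrame, y_true: np.ndarray, scores: np.ndarray, config: RunConfig
):
    report = binary_metrics(y_true, (scores >= config.decision_threshold).astype(int))
    auc = float("nan")
    if len(np.unique(y_true)) == 2:
        auc, _ = roc_auc(y_true, scores)
    accuracy = float(
        (severity["label_reference"] == severity["label_estimated"]).mean()
    )
    rho = float("nan")
    if (
        len(severity) >= 2
        and severity["ahi_reference"].nunique() > 1
        and severity["ahi_estimated"].nunique() > 1
    ):
        rho = float(
            spearmanr(severity["ahi_reference"], severity["ahi_estimated"]).statistic
        )
    return report, auc, accuracy, rho


def run_pipeline(
    nights: list[NightInput], config: RunConfig | None = None, encoder=None
) -> PipelineResult:
    """One seeded 80/20 night split: fit on the training nights, grade
    the held-out nights."""
    config = config or RunConfig()
    encoder = encoder or make_encoder(config)
    train, test = split_nights(nights, config)
    mfcc = {n.night_id: _night_features(n, config) for n in nights}
    model, rows, y_true, scores = _fit_and_grade(train, test, mfcc, config, encoder)
    severity = pd.DataFrame(rows)
    report, auc, accuracy, rho = _summarize(severity, y_true, scores, config)
    return PipelineResult(
        severity_table=severity,
        minute_metrics=report,
        minute_auc=auc,
        severity_accuracy=accuracy,
        ahi_rank_correlation=rho,
        model=model,
        train_ids=[n.night_id for n in train],
        test_ids=[n.night_id for n in test],
    )


def cross_fit_pipeline(
    nights: list[NightInput], config: RunConfig | None = None, encoder=None,
    n_folds: int = 6,
) -> PipelineResult:
    """Grade every night while held out, via round-robin folds.

    The nights are dealt into ``n_folds`` severity-stratified folds; each
    fold is graded by a model fitted on the remaining nights (for six
    folds of a twelve-night cohort this is the same 10-train/2-test
    geometry as the single split, applied to every night in turn).  The
    summary statistics then rest on one graded row per night.
    """
    config = config or RunConfig()
    encoder = encoder or make_encoder(config)
    if n_folds < 2 or n_folds > len(nights):
        raise ValidationError(
            f"n_folds must be in [2, {len(nights)}], got {n_folds}"
        )
    mfcc = {n.night_id: _night_features(n, config) for n in nights}
    folds = _stratified_folds(nights, config, n_folds=n_folds)
    all_rows, y_parts, score_parts = [], [], []
    model = None
    for fold in folds:
        fold_set = set(fold)
        train = [n for i, n in enumerate(nights) if i not in fold_set]
        test = [n for i, n in enumerate(nights) if i in fold_set]
        model, rows, y_true, scores = _fit_and_grade(train, test, mfcc, config, encoder)
        all_rows.extend(rows)
        y_parts.append(y_true)
        score_parts.append(scores)
    severity = pd.DataFrame(all_rows).sort_values("night_id", ignore_index=True)
    y_true = np.concatenate(y_parts)
    scores = np.concatenate(score_parts)
    report, auc, accuracy, rho = _summarize(severity, y_true, scores, config)
    return PipelineResult(
        severity_table=severity,
        minute_metrics=report,
        minute_auc=auc,
        severity_accuracy=accuracy,
        ahi_rank_correlation=rho,
        model=model,
        train_ids=[],
        test_ids=[n.night_id for n in nights],
    )
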