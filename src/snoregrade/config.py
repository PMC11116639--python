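"""Run configuration: one record of every knob, YAML round-trippable.

Every run writes its resolved configuration next to its outputs so it
can be re-executed bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .classify import ClassifierConfig
from .exceptions import ConfigError

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """All pipeline parameters for one reproducible run."""

    # framing / spectral analysis
    frame_length_s: float = 0.025
    hop_length_s: float = 0.010
    window_name: str = "hamming"
    n_fft: int = 256
    n_mel_filters: int = 26
    n_mfcc: int = 13
    fmin_hz: float = 0.0
    fmax_hz: float | None = None  # None -> Nyquist of each recording
    minute_aggregation: str = "mean"
    night_calibration: bool = True  # reference minutes to the night's own snore baseline
    calibration_anchor_minutes: int = 3
    # semantic encoding
    encoder_backend: str = "deterministic_fallback"
    encoder_dim: int = 16
    sentence_precision: int = 4
    # labeling / fusion / grading
    labeling_rule: str = "event_duration"
    min_event_duration_s: float = 30.0
    fusion_mode: str = "inference_safe"
    counting_mode: str = "positive_minutes"
    decision_threshold: float = 0.5
    severity_thresholds: tuple[float, float, float] = (5.0, 15.0, 30.0)
    # split and seeding
    test_fraction: float = 0.2
    stratify_split: bool = True
    random_seed: int = 0
    # classifier
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def __post_init__(self) -> None:
        if isinstance(self.classifier, dict):
            self.classifier = ClassifierConfig(**self.classifier)
        for name in ("frame_length_s", "hop_length_s", "n_fft", "n_mel_filters",
                     "n_mfcc", "encoder_dim", "min_event_duration_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_mfcc > self.n_mel_filters:
            raise ConfigError(
                f"n_mfcc ({self.n_mfcc}) must not exceed n_mel_filters "
                f"({self.n_mel_filters})"
            )
        if self.fmax_hz is not None and self.fmin_hz >= self.fmax_hz:
            raise ConfigError(f"need fmin_hz < fmax_hz, got {self.fmin_hz} >= {self.fmax_hz}")
        if not 0 < self.test_fraction < 1:
            raise ConfigError(f"test_fraction must be in (0, 1), got {self.test_fraction}")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["severity_thresholds"] = list(self.severity_thresholds)
        return out


def load_config(path: str) -> RunConfig:
    """Read a YAML mirror of :class:`RunConfig`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "severity_thresholds" in payload:
        payload["severity_thresholds"] = tuple(payload["severity_thresholds"])
    return RunConfig(**payload)


def save_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
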