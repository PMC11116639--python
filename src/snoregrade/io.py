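"""File formats and night segmentation.

The pipeline touches four kinds of artifact:

* mono PCM WAV overnight recordings (read via :mod:`scipy.io.wavfile`,
  samples rescaled to ``[-1, 1]``, never resampled on read);
* apnea-event annotation tables — TSV with a named header
  (``start_s``, ``end_s``, ``kind``), ``#``-comments allowed;
* per-minute feature matrices, persisted either as TSV (diffable) or as
  an ``.npz`` container (compact);
* hour-long processing segments of a night.

Times are seconds from recording start; intervals are half-open
``[start_s, end_s)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .exceptions import (
    FormatError,
    InputError,
    UnsupportedFormatError,
    ValidationError,
)

__all__ = [
    "AudioRecording",
    "ApneaEvent",
    "EventList",
    "HourSegment",
    "read_wav",
    "write_wav",
    "read_annotations",
    "write_annotations",
    "segment_hours",
    "read_feature_matrix",
    "write_feature_matrix",
]


@dataclass
class AudioRecording:
    """A sampled mono waveform, amplitudes in ``[-1, 1]``."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise UnsupportedFormatError(
                f"expected mono audio, got {self.samples.ndim} dimensions"
            )
        if self.sample_rate <= 0:
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class ApneaEvent:
    """An annotated interval of breathing cessation, ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    kind: str = "apnea"

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"event end ({self.end_s}) must be after start ({self.start_s})"
            )
        if self.start_s < 0:
            raise ValidationError(f"event start must be >= 0, got {self.start_s}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EventList:
    """Sorted, merged apnea events for one night."""

    events: list[ApneaEvent]
    night_duration_s: float

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.end_s > self.night_duration_s + 1e-9:
                raise ValidationError(
                    f"event ({ev.start_s}, {ev.end_s}) extends past night end "
                    f"({self.night_duration_s} s)"
                )
        self.events = merge_events(self.events)

    @property
    def apnea_events(self) -> list[ApneaEvent]:
        return [ev for ev in self.events if ev.kind == "apnea"]


def merge_events(events: list[ApneaEvent]) -> list[ApneaEvent]:
    """Sort by start and merge overlapping/touching intervals of equal kind."""
    merged: list[ApneaEvent] = []
    for ev in sorted(events, key=lambda e: (e.start_s, e.end_s)):
        if merged and ev.kind == merged[-1].kind and ev.start_s <= merged[-1].end_s:
            last = merged.pop()
            ev = ApneaEvent(last.start_s, max(last.end_s, ev.end_s), ev.kind)
        merged.append(ev)
    return merged


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------

_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


def read_wav(path: str | os.PathLike) -> AudioRecording:
    """Read a mono PCM WAV file; samples rescaled to ``[-1, 1]``.

    No resampling is performed: the header sample rate is returned as-is.
    Multi-channel or compressed files raise :class:`UnsupportedFormatError`.
    """
    if not os.path.exists(path):
        raise InputError(f"no such audio file: {path}")
    try:
        sr, data = wavfile.read(path)
    except ValueError as exc:  # compressed / unknown codec
        raise UnsupportedFormatError(f"{path}: {exc}") from exc
    if data.ndim != 1:
        raise UnsupportedFormatError(
            f"{path}: expected mono audio, found {data.shape[1]} channels"
        )
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise UnsupportedFormatError(f"{path}: unsupported sample dtype {data.dtype}")
    return AudioRecording(samples=samples, sample_rate=int(sr))


def write_wav(path: str | os.PathLike, rec: AudioRecording, bit_depth: int = 16) -> None:
    """Write a recording as mono PCM WAV (8 or 16 bit)."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    if bit_depth == 16:
        data = np.round(clipped * 32767.0).astype(np.int16)
    elif bit_depth == 8:
        # inverse of the read scaling (x - 128) / 128
        data = np.clip(np.round(clipped * 128.0) + 128.0, 0, 255).astype(np.uint8)
    else:
        raise ValidationError(f"bit_depth must be 8 or 16, got {bit_depth}")
    wavfile.write(path, rec.sample_rate, data)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_ANNOT_COLUMNS = ["start_s", "end_s", "kind"]


def read_annotations(
    path: str | os.PathLike, night_duration_s: float | None = None
) -> EventList:
    """Read a TSV annotation table into a sorted, merged :class:`EventList`.

    Columns ``start_s`` (float), ``end_s`` (float), ``kind`` (string), one
    event per row; lines starting with ``#`` are comments.  The night
    duration is taken from the argument (usually the companion audio), from
    an optional ``night_duration_s`` column, or — failing both — from the
    last event end rounded up to a whole minute.
    """
    if not os.path.exists(path):
        raise InputError(f"no such annotation file: {path}")
    try:
        table = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ValidationError(f"{path}: cannot parse as TSV ({exc})") from exc
    missing = [c for c in _ANNOT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")

    events = []
    for i, row in table.iterrows():
        try:
            start, end = float(row["start_s"]), float(row["end_s"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path} row {i + 1}: unparseable number") from exc
        if not np.isfinite(start) or not np.isfinite(end):
            raise ValidationError(f"{path} row {i + 1}: non-finite time")
        if end <= start:
            raise ValidationError(
                f"{path} row {i + 1}: end_s ({end}) must exceed start_s ({start})"
            )
        events.append(ApneaEvent(start, end, str(row["kind"])))

    if night_duration_s is None and "night_duration_s" in table.columns:
        night_duration_s = float(table["night_duration_s"].iloc[0])
    if night_duration_s is None:
        last_end = max((ev.end_s for ev in events), default=0.0)
        night_duration_s = float(np.ceil(last_end / 60.0) * 60.0) or 60.0
    return EventList(events=events, night_duration_s=night_duration_s)


def write_annotations(path: str | os.PathLike, events: EventList) -> None:
    """Write an :class:`EventList` as the TSV dialect read_annotations reads."""
    with open(path, "w") as fh:
        fh.write(f"# night_duration_s: {events.night_duration_s}\n")
        fh.write("start_s\tend_s\tkind\tnight_duration_s\n")
        for ev in events.events:
            fh.write(
                f"{ev.start_s!r}\t{ev.end_s!r}\t{ev.kind}\t{events.night_duration_s!r}\n"
            )


# ---------------------------------------------------------------------------
# Hour segmentation
# ---------------------------------------------------------------------------


@dataclass
class HourSegment:
    """One hour-long slice of a night; the trailing slice may be partial."""

    recording: AudioRecording
    index: int
    is_partial: bool = field(default=False)


def segment_hours(rec: AudioRecording) -> list[HourSegment]:
    """Split a night into consecutive 3600-s segments.

    A trailing partial segment is kept and flagged so nights shorter than
    a whole number of hours remain gradable.  Concatenating the segments
    reproduces the input exactly.
    """
    if rec.duration_seconds < 1.0:
        raise ValidationError("recording must be at least 1 s long")
    samples_per_hour = 3600 * rec.sample_rate
    segments = []
    for i, off in enumerate(range(0, rec.n_samples, samples_per_hour)):
        chunk = rec.samples[off : off + samples_per_hour]
        segments.append(
            HourSegment(
                recording=AudioRecording(chunk, rec.sample_rate),
                index=i,
                is_partial=len(chunk) < samples_per_hour,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------


def write_feature_matrix(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    """Persist a labeled numeric matrix losslessly.

    ``.tsv`` → delimited text (floats written at full repr precision);
    ``.npz`` → NumPy container with values, index and column labels.
    """
    if matrix.size == 0:
        raise ValidationError("refusing to write an empty feature matrix")
    path = os.fspath(path)
    if path.endswith(".npz"):
        np.savez(
            path,
            values=matrix.to_numpy(dtype=np.float64),
            index=np.asarray(matrix.index, dtype=str),
            columns=np.asarray(matrix.columns, dtype=str),
            index_name=np.asarray([matrix.index.name or ""]),
        )
    else:
        matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "row")


def read_feature_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a matrix written by :func:`write_feature_matrix`."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such feature matrix: {path}")
    if path.endswith(".npz"):
        with np.load(path, allow_pickle=False) as npz:
            df = pd.DataFrame(
                npz["values"], index=npz["index"], columns=npz["columns"]
            )
            name = str(npz["index_name"][0])
            df.index.name = name or None
            try:
                df.index = df.index.astype(int)
            except (TypeError, ValueError):
                pass
            return df
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"{path}: cannot read feature matrix ({exc})") from exc
    if df.size == 0:
        raise FormatError(f"{path}: empty feature matrix")
    return df
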