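"""Per-minute binary apnea-event records.

Annotated apnea intervals become a length-T binary vector
``E = [e_1, ..., e_T]`` (T = minutes in the night, 480 for a full 8-h
recording), with ``e_t = 1`` marking an apnea minute.  The clinical
convention implemented is the 30-second rule, in two readings:

* ``event_duration`` (default): minute ``t`` is positive iff some apnea
  event whose *total* duration is >= 30 s overlaps ``[60(t-1), 60t)``.
* ``within_minute_overlap``: minute ``t`` is positive iff the apnea
  overlap *inside* the minute itself is >= 30 s.

The duration reading is the default: under the overlap reading a 30-59 s
event straddling a minute boundary would silently produce no positive
minute at all.  The threshold comparison is inclusive (>= 30 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import EventList

__all__ = ["EventRecord", "label_minutes", "event_record_to_table", "table_to_event_record"]

RULES = ("event_duration", "within_minute_overlap")


@dataclass
class EventRecord:
    """Binary per-minute labels for one night."""

    labels: np.ndarray
    rule: str = "event_duration"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValidationError("event record must be one-dimensional")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("event record values must be 0 or 1")
        self.labels = self.labels.astype(np.int8)
        if self.rule not in RULES:
            raise ValidationError(f"unknown rule {self.rule!r}; choose from {RULES}")

    @property
    def n_minutes(self) -> int:
        return len(self.labels)


def label_minutes(
    events: EventList, rule: str = "event_duration", min_duration_s: float = 30.0
) -> EventRecord:
    """Apply the 30-second rule to annotated events.

    Minutes are 1-based with half-open extents ``[60(t-1), 60t)``;
    ``T = ceil(night_duration_s / 60)``.  Only events of kind ``"apnea"``
    contribute.  An event outside the night bounds is rejected by
    :class:`~snoregrade.io.EventList` itself.
    """
    if rule not in RULES:
        raise ValidationError(f"unknown rule {rule!r}; choose from {RULES}")
    n_minutes = int(np.ceil(events.night_duration_s / 60.0))
    labels = np.zeros(n_minutes, dtype=np.int8)
    starts = np.arange(n_minutes) * 60.0
    ends = starts + 60.0
    total_overlap = np.zeros(n_minutes)
    for ev in events.apnea_events:
        overlap = np.clip(
            np.minimum(ends, ev.end_s) - np.maximum(starts, ev.start_s), 0.0, None
        )
        if rule == "event_duration":
            if ev.duration_s >= min_duration_s:
                labels[overlap > 0] = 1
        else:
            total_overlap += overlap
    if rule == "within_minute_overlap":
        labels[total_overlap >= min_duration_s] = 1
    return EventRecord(labels=labels, rule=rule)


def event_record_to_table(record: EventRecord) -> pd.DataFrame:
    """Two-column (minute, label) table; lossless round trip."""
    return pd.DataFrame(
        {
            "minute": np.arange(1, record.n_minutes + 1),
            "label": record.labels.astype(int),
        }
    )


def table_to_event_record(table: pd.DataFrame, rule: str = "event_duration") -> EventRecord:
    """Inverse of :func:`event_record_to_table`; validates binary labels."""
    if "label" not in table.columns:
        raise ValidationError("event-record table needs a 'label' column")
    labels = table.sort_values("minute")["label"].to_numpy() if "minute" in table.columns \
        else table["label"].to_numpy()
    bad = ~np.isin(labels, (0, 1))
    if bad.any():
        raise ValidationError(
            f"non-binary labels at rows {np.flatnonzero(bad).tolist()}"
        )
    return EventRecord(labels=labels, rule=rule)
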