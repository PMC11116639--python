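"""Synthetic overnight snore recordings with embedded apnea events.

The generator emulates the kind of bedside recording the pipeline is
built for: breath-synchronous snore bursts — a harmonic stack at a
per-night fundamental (80-150 Hz), amplitude-modulated by a per-breath
envelope — over a white background-noise floor.  An apnea event is an
interval in which snoring is silenced while the noise floor remains;
events are placed uniformly at random without overlap, their count is
``round(target_ahi * hours)`` and their durations are drawn uniformly
from a configured range (default 20-90 s, so both sub-30-s events, which
the 30-second rule leaves unlabeled, and longer labeled events occur).

What this emulates: the acoustic contrast between snoring and apneic
silence that makes minute-level MFCC features informative.  What it does
not: real snore timbre, gasps on breathing resumption, body movement,
room acoustics, or physiological signals — results on this audio bound
nothing about clinical recordings.

Everything is reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import PackingError, ValidationError
from .io import ApneaEvent, AudioRecording, EventList
from .labeling import EventRecord, label_minutes

__all__ = [
    "SyntheticNightSpec",
    "SyntheticNight",
    "SHORT_TEST_SPEC",
    "COHORT_CLASS_AHI_RANGES",
    "place_events",
    "simulate_night",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SyntheticNightSpec:
    """Study conditions for one synthetic night.

    Defaults mirror an 8-h overnight recording at 8 kHz; a reduced
    profile (:data:`SHORT_TEST_SPEC`) keeps the full audio path fast
    enough for unit tests.
    """

    duration_min: float = 480.0
    sample_rate: int = 8000
    target_ahi: float = 15.0
    apnea_duration_s: tuple[float, float] = (20.0, 90.0)
    breath_period_s: float = 4.0
    snore_fundamental_hz: tuple[float, float] = (80.0, 150.0)
    snore_band_gain: float = 0.3
    background_noise_sd: float = 0.01
    min_gap_s: float = 5.0
    labeling_rule: str = "event_duration"

    def __post_init__(self) -> None:
        if self.target_ahi < 0:
            raise ValidationError(f"target_ahi must be >= 0, got {self.target_ahi}")
        if self.duration_min <= 0 or self.sample_rate <= 0:
            raise ValidationError("duration and sample rate must be positive")
        lo, hi = self.apnea_duration_s
        if not 0 < lo <= hi:
            raise ValidationError(f"bad apnea duration range ({lo}, {hi})")

    @property
    def duration_s(self) -> float:
        return self.duration_min * 60.0

    @property
    def duration_hours(self) -> float:
        return self.duration_min / 60.0


#: reduced profile: 20-minute night at 4 kHz, runs in seconds
SHORT_TEST_SPEC = SyntheticNightSpec(duration_min=20.0, sample_rate=4000)


@dataclass
class SyntheticNight:
    """A generated night: audio, ground-truth events, and bookkeeping."""

    audio: AudioRecording
    events: EventList
    truth_record: EventRecord
    realized_ahi: float
    spec: SyntheticNightSpec
    seed: int
    severity_class: int | None = field(default=None)


def place_events(spec: SyntheticNightSpec, rng: np.random.Generator) -> EventList:
    """Place ``round(target_ahi * hours)`` non-overlapping apnea intervals.

    Durations are uniform from the configured range; positions uniform at
    random with a minimum inter-event gap.  If the drawn durations cannot
    fit, durations are redrawn a few times before failing with the
    limiting quantity.
    """
    n_events = int(round(spec.target_ahi * spec.duration_hours))
    if n_events == 0:
        return EventList(events=[], night_duration_s=spec.duration_s)
    lo, hi = spec.apnea_duration_s
    for _ in range(20):
        durations = rng.uniform(lo, hi, n_events)
        occupied = durations.sum() + spec.min_gap_s * (n_events - 1)
        if occupied < spec.duration_s:
            break
    else:
        raise PackingError(
            f"{n_events} events of mean duration {(lo + hi) / 2:.0f} s plus "
            f"{spec.min_gap_s} s gaps exceed the {spec.duration_s:.0f} s night"
        )
    # distribute the free space as n_events + 1 random gaps
    free = spec.duration_s - durations.sum() - spec.min_gap_s * (n_events - 1)
    cuts = np.sort(rng.uniform(0.0, free, n_events))
    starts = cuts + np.concatenate(
        [[0.0], np.cumsum(durations[:-1] + spec.min_gap_s)]
    )
    events = [
        ApneaEvent(float(s), float(s + d), "apnea")
        for s, d in zip(starts, durations)
    ]
    return EventList(events=events, night_duration_s=spec.duration_s)


def _synthesize_audio(
    spec: SyntheticNightSpec, events: EventList, rng: np.random.Generator
) -> AudioRecording:
    n = int(round(spec.duration_s * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate

    # per-breath envelope: a squared half-sine burst in the first 40% of
    # each breath cycle (inspiration), silence for the rest
    phase = (t % spec.breath_period_s) / spec.breath_period_s
    duty = 0.4
    envelope = np.where(
        phase < duty, np.sin(np.pi * phase / duty) ** 2, 0.0
    )

    f0 = rng.uniform(*spec.snore_fundamental_hz)
    harmonics = np.zeros(n)
    for h in range(1, 6):
        harmonics += np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi)) / h
    snore = spec.snore_band_gain * envelope * harmonics

    # silence the snore (noise floor remains) inside every apnea interval
    mask = np.ones(n)
    for ev in events.apnea_events:
        i0 = int(np.floor(ev.start_s * spec.sample_rate))
        i1 = int(np.ceil(ev.end_s * spec.sample_rate))
        mask[i0:i1] = 0.0
    samples = snore * mask + rng.normal(0.0, spec.background_noise_sd, n)

    peak = np.abs(samples).max()
    if peak > 0.95:
        samples *= 0.95 / peak
    return AudioRecording(samples=samples, sample_rate=spec.sample_rate)


def simulate_night(spec: SyntheticNightSpec, seed: int) -> SyntheticNight:
    """Generate one night; bit-identical given the same ``(spec, seed)``."""
    rng = np.random.default_rng(seed)
    events = place_events(spec, rng)
    audio = _synthesize_audio(spec, events, rng)
    truth = label_minutes(events, rule=spec.labeling_rule)
    return SyntheticNight(
        audio=audio,
        events=events,
        truth_record=truth,
        realized_ahi=len(events.apnea_events) / spec.duration_hours,
        spec=spec,
        seed=seed,
    )


#: per-class target-AHI ranges used when drawing a cohort.  Interior to
#: the severity bins because the realized AHI is quantized: one event in
#: a 20-minute night is 3 events/h, so a target at a bin edge could
#: round into the neighboring class.  The severe range is capped at
#: 40 events/h so the drawn events stay packable in the short profile.
COHORT_CLASS_AHI_RANGES = {
    0: (0.5, 4.0),
    1: (6.0, 13.0),
    2: (16.0, 28.0),
    3: (30.0, 40.0),
}


def simulate_cohort(
    n_nights: int,
    severity_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    spec_template: SyntheticNightSpec = SHORT_TEST_SPEC,
) -> list[SyntheticNight]:
    """Generate a cohort of nights with a given severity-class mix.

    Class counts follow the mix by largest remainder; per-night target
    AHIs are drawn uniformly from within-class ranges and per-night seeds
    derive deterministically from the master seed.
    """
    if n_nights < 1:
        raise ValidationError(f"n_nights must be >= 1, got {n_nights}")
    mix = np.asarray(severity_mix, dtype=np.float64)
    if mix.shape != (4,) or (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
        raise ValidationError(
            f"severity_mix must be four non-negative proportions summing to 1, got {severity_mix}"
        )
    ideal = mix * n_nights
    counts = np.floor(ideal).astype(int)
    for i in np.argsort(-(ideal - counts))[: n_nights - counts.sum()]:
        counts[i] += 1

    rng = np.random.default_rng(seed)
    night_seeds = rng.integers(0, 2**31 - 1, size=n_nights)
    classes = np.repeat(np.arange(4), counts)
    nights = []
    for i, (cls, night_seed) in enumerate(zip(classes, night_seeds)):
        lo, hi = COHORT_CLASS_AHI_RANGES[int(cls)]
        target = rng.uniform(lo, hi)
        spec = replace(spec_template, target_ahi=float(target))
        night = simulate_night(spec, int(night_seed))
        night.severity_class = int(cls)
        nights.append(night)
    return nights
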