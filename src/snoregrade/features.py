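"""Mel-frequency cepstral features for overnight snoring audio.

The chain is the classical one: frame and window the signal, take the
one-sided FFT power spectrum, pool it through a triangular Mel filter
bank, take logarithms, and decorrelate with a cosine transform

    C_l = sum_{m=1}^{M} M_m * cos(pi * l * (m - 1/2) / M),   l = 1..L,

i.e. a DCT-II without orthonormal scaling, keeping L = 13 static
coefficients per frame (no C_0 energy term, no delta coefficients).
Frame-level vectors are then aggregated to one vector per minute of the
night, and standardized to zero mean / unit variance with statistics
fitted on training nights only.

Defaults: 25 ms frames, 10 ms hop, Hamming window, 256-point FFT,
26 Mel filters spanning 0 Hz to Nyquist, HTK Mel mapping
``m = 2595 * log10(1 + f / 700)``, natural log with floor 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.preprocessing import StandardScaler

from .exceptions import ConfigError, TooShortError, ValidationError
from .io import AudioRecording

__all__ = [
    "FrameSpec",
    "MelFilterBank",
    "LOG_FLOOR_EPS",
    "frame_and_window",
    "power_spectrum",
    "hz_to_mel",
    "mel_to_hz",
    "build_mel_filterbank",
    "mel_log_energies",
    "dct_cepstrum",
    "minute_mfcc",
    "minute_loudness",
    "calibrate_to_night",
    "standardize_features",
]

#: floor added inside the log to guard log(0) on silent filters
LOG_FLOOR_EPS = 1e-10

_WINDOWS = {
    "hamming": np.hamming,
    "hann": np.hanning,
    "rect": np.ones,
}


@dataclass(frozen=True)
class FrameSpec:
    """Analysis frame geometry, in samples."""

    frame_length: int
    hop_length: int
    window_name: str = "hamming"

    def __post_init__(self) -> None:
        if not 0 < self.hop_length <= self.frame_length:
            raise ConfigError(
                f"need 0 < hop_length <= frame_length, got hop={self.hop_length} "
                f"frame={self.frame_length}"
            )
        if self.window_name not in _WINDOWS:
            raise ConfigError(
                f"unknown window {self.window_name!r}; choose from {sorted(_WINDOWS)}"
            )

    def window(self) -> np.ndarray:
        return _WINDOWS[self.window_name](self.frame_length)

    @classmethod
    def from_seconds(
        cls, frame_length_s: float, hop_length_s: float, sample_rate: int,
        window_name: str = "hamming",
    ) -> "FrameSpec":
        return cls(
            frame_length=int(round(frame_length_s * sample_rate)),
            hop_length=int(round(hop_length_s * sample_rate)),
            window_name=window_name,
        )


def frame_and_window(rec: AudioRecording, spec: FrameSpec) -> np.ndarray:
    """Slice a recording into overlapping windowed frames.

    Returns an ``(n_frames, frame_length)`` array with
    ``n_frames = floor((n_samples - frame_length) / hop_length) + 1``;
    frame ``i`` starts at sample ``i * hop_length`` and is multiplied
    elementwise by the window.
    """
    if rec.n_samples < spec.frame_length:
        raise TooShortError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"frame ({spec.frame_length} samples)"
        )
    frames = sliding_window_view(rec.samples, spec.frame_length)[:: spec.hop_length]
    return frames * spec.window()


def power_spectrum(frames: np.ndarray, n_fft: int) -> np.ndarray:
    """One-sided FFT power spectrum |X(k)|², k = 0..n_fft/2.

    ``X(k) = sum_n x(n) exp(-j 2 pi n k / n_fft)`` with the frame
    zero-padded up to ``n_fft``.  Accepts a single frame or a matrix of
    frames (transform along the last axis).  ``n_fft`` must be a positive
    power of two (fast-transform requirement).
    """
    frames = np.asarray(frames, dtype=np.float64)
    if n_fft <= 0 or (n_fft & (n_fft - 1)) != 0:
        raise ConfigError(f"n_fft must be a positive power of two, got {n_fft}")
    if frames.shape[-1] > n_fft:
        raise ConfigError(
            f"frame length {frames.shape[-1]} exceeds n_fft {n_fft}"
        )
    spectrum = np.fft.rfft(frames, n=n_fft, axis=-1)
    return np.abs(spectrum) ** 2


def hz_to_mel(f_hz):
    """HTK Mel mapping ``m = 2595 * log10(1 + f / 700)``; strictly increasing."""
    f_hz = np.asarray(f_hz, dtype=np.float64)
    if np.any(f_hz < 0):
        raise ValidationError("frequency must be >= 0 Hz")
    return 2595.0 * np.log10(1.0 + f_hz / 700.0)


def mel_to_hz(mel):
    """Inverse of :func:`hz_to_mel`."""
    mel = np.asarray(mel, dtype=np.float64)
    if np.any(mel < 0):
        raise ValidationError("mel value must be >= 0")
    return 700.0 * (10.0 ** (mel / 2595.0) - 1.0)


@dataclass
class MelFilterBank:
    """Triangular Mel filters sampled at the one-sided FFT bin frequencies."""

    weights: np.ndarray  # (M, n_fft//2 + 1), responses in [0, 1]
    center_freqs_hz: np.ndarray
    n_fft: int
    sample_rate: int

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]


def build_mel_filterbank(
    n_filters: int,
    sample_rate: int,
    n_fft: int,
    fmin_hz: float = 0.0,
    fmax_hz: float | None = None,
) -> MelFilterBank:
    """Build ``n_filters`` triangular filters with apexes equally spaced in Mel.

    ``n_filters + 2`` anchor points are spaced uniformly on the Mel axis
    between ``fmin_hz`` and ``fmax_hz``; filter ``m`` rises linearly from
    anchor ``m-1`` to 1 at anchor ``m`` and falls to zero at anchor ``m+1``.
    Adjacent filters overlap by construction.
    """
    if fmax_hz is None:
        fmax_hz = sample_rate / 2.0
    if n_filters < 2:
        raise ConfigError(f"need at least 2 filters, got {n_filters}")
    if not fmin_hz < fmax_hz:
        raise ConfigError(f"need fmin < fmax, got {fmin_hz} >= {fmax_hz}")
    if fmax_hz > sample_rate / 2.0 + 1e-9:
        raise ConfigError(
            f"fmax {fmax_hz} Hz exceeds Nyquist {sample_rate / 2.0} Hz"
        )
    anchors_mel = np.linspace(hz_to_mel(fmin_hz), hz_to_mel(fmax_hz), n_filters + 2)
    anchors_hz = mel_to_hz(anchors_mel)
    bin_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft

    lower, center, upper = anchors_hz[:-2], anchors_hz[1:-1], anchors_hz[2:]
    rising = (bin_freqs[None, :] - lower[:, None]) / (center - lower)[:, None]
    falling = (upper[:, None] - bin_freqs[None, :]) / (upper - center)[:, None]
    weights = np.clip(np.minimum(rising, falling), 0.0, None)
    return MelFilterBank(
        weights=weights,
        center_freqs_hz=center,
        n_fft=n_fft,
        sample_rate=sample_rate,
    )


def mel_log_energies(
    power: np.ndarray, bank: MelFilterBank, eps: float = LOG_FLOOR_EPS
) -> np.ndarray:
    """Pool a power spectrum through the bank and take natural logs.

    ``S_m = sum_k |X(k)|^2 H_m(k)``, ``M_m = log(S_m + eps)``.  Accepts a
    single spectrum or a matrix of spectra (last axis = frequency bins).
    """
    power = np.asarray(power, dtype=np.float64)
    if power.shape[-1] != bank.weights.shape[1]:
        raise ValidationError(
            f"spectrum has {power.shape[-1]} bins but the bank was built for "
            f"{bank.weights.shape[1]} (n_fft={bank.n_fft})"
        )
    energies = power @ bank.weights.T
    return np.log(energies + eps)


def dct_cepstrum(log_energies: np.ndarray, n_coeffs: int) -> np.ndarray:
    """Cepstral coefficients ``C_l = sum_m M_m cos(pi l (m - 1/2) / M)``.

    ``l`` runs 1..n_coeffs (no energy term); DCT-II without orthonormal
    scaling.  Accepts a single log-energy vector or a matrix (last axis = M).
    """
    log_energies = np.asarray(log_energies, dtype=np.float64)
    n_mel = log_energies.shape[-1]
    if n_coeffs > n_mel:
        raise ConfigError(
            f"cannot keep {n_coeffs} coefficients from {n_mel} filters"
        )
    m = np.arange(1, n_mel + 1)
    ell = np.arange(1, n_coeffs + 1)
    basis = np.cos(np.pi * np.outer(ell, m - 0.5) / n_mel)  # (L, M)
    return log_energies @ basis.T


_AGGREGATIONS = ("mean", "median", "mean_std")


def minute_mfcc(
    rec: AudioRecording,
    frame_spec: FrameSpec | None = None,
    n_fft: int = 256,
    n_mel_filters: int = 26,
    n_mfcc: int = 13,
    fmin_hz: float = 0.0,
    fmax_hz: float | None = None,
    aggregation: str = "mean",
    log_eps: float = LOG_FLOOR_EPS,
) -> pd.DataFrame:
    """Per-minute MFCC aggregates for a whole night.

    Frame-level coefficients are grouped by the minute containing each
    frame's *start* sample and aggregated per coefficient (default: mean).
    Returns a ``T x L`` DataFrame indexed by 1-based minute, where
    ``T = ceil(duration / 60 s)``; a minute containing no frame start is
    filled with zeros.
    """
    if aggregation not in _AGGREGATIONS:
        raise ConfigError(
            f"unknown aggregation {aggregation!r}; choose from {_AGGREGATIONS}"
        )
    if frame_spec is None:
        frame_spec = FrameSpec.from_seconds(0.025, 0.010, rec.sample_rate)
    frames = frame_and_window(rec, frame_spec)
    power = power_spectrum(frames, n_fft)
    bank = build_mel_filterbank(n_mel_filters, rec.sample_rate, n_fft, fmin_hz, fmax_hz)
    coeffs = dct_cepstrum(mel_log_energies(power, bank, eps=log_eps), n_mfcc)

    starts = np.arange(len(frames)) * frame_spec.hop_length
    minute_of_frame = starts // (60 * rec.sample_rate)
    n_minutes = int(np.ceil(rec.duration_seconds / 60.0))

    columns = [f"mfcc_{i:02d}" for i in range(1, n_mfcc + 1)]
    if aggregation == "mean_std":
        columns = columns + [f"mfcc_{i:02d}_std" for i in range(1, n_mfcc + 1)]
    out = np.zeros((n_minutes, len(columns)))
    for t in range(n_minutes):
        block = coeffs[minute_of_frame == t]
        if len(block) == 0:
            continue  # empty minute stays all-zero
        if aggregation == "mean":
            out[t] = block.mean(axis=0)
        elif aggregation == "median":
            out[t] = np.median(block, axis=0)
        else:
            out[t] = np.concatenate([block.mean(axis=0), block.std(axis=0)])
    return pd.DataFrame(
        out, index=pd.RangeIndex(1, n_minutes + 1, name="minute"), columns=columns
    )


def minute_loudness(rec: AudioRecording) -> np.ndarray:
    """Log mean squared amplitude per minute (a per-minute loudness proxy).

    Used to pick each night's snore-dominated anchor minutes for
    :func:`calibrate_to_night`; minutes silenced by apnea sit far below
    the night's loudest minutes on this scale.
    """
    n_minutes = int(np.ceil(rec.duration_seconds / 60.0))
    samples_per_minute = 60 * rec.sample_rate
    out = np.empty(n_minutes)
    for t in range(n_minutes):
        chunk = rec.samples[t * samples_per_minute : (t + 1) * samples_per_minute]
        out[t] = np.log(np.mean(chunk**2) + LOG_FLOOR_EPS)
    return out


def calibrate_to_night(
    matrix: pd.DataFrame, loudness: np.ndarray, n_anchor: int = 3
) -> pd.DataFrame:
    """Reference each minute's features against the night's own snore baseline.

    Subtracts the mean feature vector of the night's ``n_anchor`` loudest
    minutes (snore-dominated in any night that is not wall-to-wall apnea)
    from every row.  Snore timbre — fundamental frequency, harmonic
    balance — varies between patients; referencing against the same
    recording makes the features express *deviation from that night's
    snoring* rather than absolute spectral shape, so a model trained on a
    few nights transfers to recordings whose timbre it never saw.
    """
    if len(loudness) != len(matrix):
        raise ValidationError(
            f"loudness has {len(loudness)} minutes but the matrix has {len(matrix)}"
        )
    if n_anchor < 1:
        raise ValidationError(f"n_anchor must be >= 1, got {n_anchor}")
    n_anchor = min(n_anchor, len(matrix))
    anchor_rows = np.argsort(loudness)[-n_anchor:]
    baseline = matrix.iloc[anchor_rows].mean(axis=0)
    return matrix - baseline


def standardize_features(
    train_matrix: pd.DataFrame, *apply_matrices: pd.DataFrame
) -> tuple[StandardScaler, pd.DataFrame, ...]:
    """Fit a zero-mean/unit-variance scaler on training rows only.

    Returns ``(scaler, standardized_train, standardized_apply...)``.  The
    scaler uses the population standard deviation; constant columns get a
    unit divisor instead of blowing up.  Statistics come from the training
    matrix alone so held-out nights see no information leak.
    """
    if len(train_matrix) < 1:
        raise ValidationError("cannot fit a scaler on zero rows")
    scaler = StandardScaler()
    scaler.fit(train_matrix.to_numpy(dtype=np.float64))
    results = []
    for df in (train_matrix, *apply_matrices):
        if list(df.columns) != list(train_matrix.columns):
            raise ValidationError("column mismatch between train and apply matrices")
        values = scaler.transform(df.to_numpy(dtype=np.float64))
        results.append(pd.DataFrame(values, index=df.index, columns=df.columns))
    return (scaler, *results)
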