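"""The MFCC chain against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from snoregrade.exceptions import ConfigError, TooShortError, ValidationError
from snoregrade.features import (
    LOG_FLOOR_EPS,
    FrameSpec,
    build_mel_filterbank,
    calibrate_to_night,
    dct_cepstrum,
    frame_and_window,
    hz_to_mel,
    mel_log_energies,
    mel_to_hz,
    minute_loudness,
    minute_mfcc,
    power_spectrum,
    standardize_features,
)
from snoregrade.io import AudioRecording


def naive_dft_power(frame, n_fft):
    """O(N^2) direct evaluation of the one-sided |X(k)|^2."""
    x = np.zeros(n_fft)
    x[: len(frame)] = frame
    n = np.arange(n_fft)
    out = []
    for k in range(n_fft // 2 + 1):
        xk = np.sum(x * np.exp(-2j * np.pi * n * k / n_fft))
        out.append(abs(xk) ** 2)
    return np.array(out)


def naive_dct(log_energies, n_coeffs):
    """Brute-force double loop over the cepstral cosine sum."""
    M = len(log_energies)
    out = []
    for ell in range(1, n_coeffs + 1):
        acc = 0.0
        for m in range(1, M + 1):
            acc += log_energies[m - 1] * np.cos(np.pi * ell * (m - 0.5) / M)
        out.append(acc)
    return np.array(out)


class TestFraming:
    @pytest.mark.parametrize(
        "n_samples,frame,hop,expected",
        [(400, 400, 160, 1), (8000, 200, 80, 98), (1000, 256, 128, 6)],
    )
    def test_frame_count_formula(self, n_samples, frame, hop, expected):
        rec = AudioRecording(np.arange(n_samples, dtype=float), 8000)
        frames = frame_and_window(rec, FrameSpec(frame, hop, "rect"))
        assert frames.shape == (expected, frame)
        # brute-force sliding loop gives the same count
        count = 0
        start = 0
        while start + frame <= n_samples:
            count += 1
            start += hop
        assert count == expected

    def test_constant_signal_rect_window_identical_frames(self):
        rec = AudioRecording(np.full(1000, 0.5), 8000)
        frames = frame_and_window(rec, FrameSpec(200, 80, "rect"))
        assert np.all(frames == frames[0])

    def test_window_applied_elementwise(self):
        rec = AudioRecording(np.ones(400), 8000)
        spec = FrameSpec(400, 160, "hamming")
        np.testing.assert_allclose(frame_and_window(rec, spec)[0], np.hamming(400))

    def test_too_short_recording(self):
        with pytest.raises(TooShortError):
            frame_and_window(AudioRecording(np.zeros(100), 8000), FrameSpec(200, 80))

    def test_bad_hop_rejected(self):
        with pytest.raises(ConfigError):
            FrameSpec(100, 0)


class TestPowerSpectrum:
    def test_zero_frame_zero_spectrum(self):
        assert np.all(power_spectrum(np.zeros(256), 256) == 0)

    def test_bin_aligned_cosine_closed_form(self):
        n_fft, k0 = 256, 16
        n = np.arange(n_fft)
        frame = np.cos(2 * np.pi * k0 * n / n_fft)
        ps = power_spectrum(frame, n_fft)
        assert ps[k0] == pytest.approx((n_fft / 2) ** 2, rel=1e-12)
        others = np.delete(ps, k0)
        assert np.max(others) < 1e-15 * ps[k0]

    def test_matches_naive_dft_on_random_frames(self, rng):
        for length in (64, 200, 256):
            frame = rng.normal(size=length)
            ps = power_spectrum(frame, 256)
            oracle = naive_dft_power(frame, 256)
            np.testing.assert_allclose(ps, oracle, rtol=1e-9, atol=1e-9)

    def test_parseval_rect_window(self, rng):
        frame = rng.normal(size=256)
        ps = power_spectrum(frame, 256)
        # double interior bins to account for the discarded mirror half
        weights = np.full(129, 2.0)
        weights[0] = weights[-1] = 1.0
        spectral = np.sum(ps * weights) / 256
        assert spectral == pytest.approx(np.sum(frame**2), rel=1e-6)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ConfigError):
            power_spectrum(np.zeros(100), 200)

    def test_frame_longer_than_n_fft_rejected(self):
        with pytest.raises(ConfigError):
            power_spectrum(np.zeros(512), 256)


class TestMelScale:
    def test_zero_fixed_point(self):
        assert hz_to_mel(0.0) == 0.0

    def test_700_hz_closed_form(self):
        assert hz_to_mel(700.0) == pytest.approx(2595 * np.log10(2), abs=1e-9)

    def test_round_trip_identity(self, rng):
        freqs = rng.uniform(0, 4000, 1000)
        np.testing.assert_allclose(mel_to_hz(hz_to_mel(freqs)), freqs, atol=1e-9)

    def test_strictly_increasing(self):
        grid = np.linspace(0, 4000, 500)
        assert np.all(np.diff(hz_to_mel(grid)) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            hz_to_mel(-1.0)


class TestFilterBank:
    def setup_method(self):
        self.bank = build_mel_filterbank(26, 8000, 512, 0.0, 4000.0)

    def test_shape_and_coverage(self):
        assert self.bank.weights.shape == (26, 257)
        bin_freqs = np.arange(257) * 8000 / 512
        first_apex, last_apex = self.bank.center_freqs_hz[[0, -1]]
        inside = (bin_freqs > first_apex) & (bin_freqs < last_apex)
        assert np.all(self.bank.weights.sum(axis=0)[inside] > 0)

    def test_rows_triangular(self):
        for row in self.bank.weights:
            support = row > 0
            assert support.any()
            diffs = np.sign(np.diff(row[support]))
            # rises then falls: at most one sign change over the support
            changes = np.count_nonzero(np.diff(diffs[diffs != 0]))
            assert changes <= 1
            assert row.max() <= 1.0 + 1e-12

    def test_apexes_equally_spaced_in_mel(self):
        mel_centers = hz_to_mel(self.bank.center_freqs_hz)
        spacing = np.diff(mel_centers)
        # recompute the spacing independently from the design band edges
        expected = (hz_to_mel(4000.0) - hz_to_mel(0.0)) / 27
        np.testing.assert_allclose(spacing, expected, atol=1e-9)

    def test_bad_band_rejected(self):
        with pytest.raises(ConfigError):
            build_mel_filterbank(26, 8000, 512, 2000.0, 1000.0)


class TestMelLogEnergies:
    def setup_method(self):
        self.bank = build_mel_filterbank(26, 8000, 256)

    def test_zero_spectrum_hits_log_floor(self):
        out = mel_log_energies(np.zeros(129), self.bank)
        np.testing.assert_allclose(out, np.log(LOG_FLOOR_EPS))

    def test_flat_spectrum_gives_row_sums(self):
        out = mel_log_energies(np.ones(129), self.bank)
        row_sums = np.array([np.sum(w) for w in self.bank.weights])
        np.testing.assert_allclose(np.exp(out) - LOG_FLOOR_EPS, row_sums, atol=1e-9)

    def test_doubling_spectrum_adds_log2(self, rng):
        ps = rng.uniform(1.0, 2.0, 129)
        delta = mel_log_energies(2 * ps, self.bank) - mel_log_energies(ps, self.bank)
        np.testing.assert_allclose(delta, np.log(2), atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mel_log_energies(np.ones(257), self.bank)


class TestDctCepstrum:
    def test_constant_input_gives_zero_cepstra(self):
        out = dct_cepstrum(np.full(26, 3.7), 13)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_single_hand_value(self):
        # M=4, energies (1,0,0,0): C_1 = cos(pi * 0.5 / 4)
        out = dct_cepstrum(np.array([1.0, 0, 0, 0]), 1)
        assert out[0] == pytest.approx(np.cos(np.pi / 8), abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_double_loop(self, seed):
        gen = np.random.default_rng(seed)
        M = int(gen.integers(4, 30))
        L = int(gen.integers(1, M + 1))
        energies = gen.normal(size=M)
        np.testing.assert_allclose(
            dct_cepstrum(energies, L), naive_dct(energies, L), atol=1e-10
        )

    def test_too_many_coefficients_rejected(self):
        with pytest.raises(ConfigError):
            dct_cepstrum(np.zeros(10), 11)


class TestMinuteMfcc:
    def _two_minute_rec(self):
        gen = np.random.default_rng(5)
        block = gen.normal(scale=0.1, size=60 * 4000)
        return AudioRecording(np.concatenate([block, block]), 4000)

    def _periodic_rec(self):
        """Two identical minutes plus one frame of lookahead so every
        frame of minute 2 mirrors a frame of minute 1 exactly."""
        gen = np.random.default_rng(5)
        block = gen.normal(scale=0.1, size=60 * 4000)
        return AudioRecording(np.concatenate([block, block, block[:100]]), 4000)

    def test_shape_and_minute_index(self):
        matrix = minute_mfcc(self._two_minute_rec())
        assert matrix.shape == (2, 13)
        assert list(matrix.index) == [1, 2]

    def test_identical_minutes_identical_rows(self):
        matrix = minute_mfcc(self._periodic_rec())
        # hop (40 samples) divides the minute and the signal repeats with
        # a 60-s period, so minutes 1 and 2 aggregate identical frames
        np.testing.assert_allclose(matrix.loc[1], matrix.loc[2], atol=1e-12)

    def test_mean_aggregation_matches_explicit_loop(self):
        rec = self._two_minute_rec()
        spec = FrameSpec.from_seconds(0.025, 0.010, rec.sample_rate)
        matrix = minute_mfcc(rec, frame_spec=spec)
        frames = frame_and_window(rec, spec)
        bank = build_mel_filterbank(26, rec.sample_rate, 256)
        per_frame = dct_cepstrum(
            mel_log_energies(power_spectrum(frames, 256), bank), 13
        )
        starts = np.arange(len(frames)) * spec.hop_length
        for t in (1, 2):
            rows = per_frame[(starts // (60 * rec.sample_rate)) == t - 1]
            np.testing.assert_allclose(
                matrix.loc[t].to_numpy(), rows.mean(axis=0), atol=1e-12
            )

    def test_pipeline_determinism_bit_identical(self):
        rec = self._two_minute_rec()
        a = minute_mfcc(rec)
        b = minute_mfcc(rec)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_unknown_aggregation_rejected(self):
        with pytest.raises(ConfigError):
            minute_mfcc(self._two_minute_rec(), aggregation="max")


class TestStandardize:
    def test_hand_computed_z_scores(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        _, std = standardize_features(train)
        np.testing.assert_allclose(
            std["a"], [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )

    def test_constant_column_no_blowup(self):
        train = pd.DataFrame({"a": [5.0, 5.0, 5.0]})
        _, std = standardize_features(train)
        np.testing.assert_array_equal(std["a"], 0.0)

    def test_no_leakage_into_test(self):
        train = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        test = pd.DataFrame({"a": [10.0, 11.0]})
        _, _, std_test = standardize_features(train, test)
        assert abs(std_test["a"].mean()) > 1.0  # far from 0: fitted on train

    def test_inverse_restores_originals(self, rng):
        train = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        scaler, std = standardize_features(train)
        np.testing.assert_allclose(
            scaler.inverse_transform(std.to_numpy()), train.to_numpy(), atol=1e-10
        )

    def test_zero_rows_rejected(self):
        with pytest.raises(ValidationError):
            standardize_features(pd.DataFrame({"a": []}))


class TestNightCalibration:
    def test_anchor_minutes_become_baseline(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        loudness = np.arange(10.0)
        out = calibrate_to_night(matrix, loudness, n_anchor=3)
        baseline = matrix.iloc[[7, 8, 9]].mean(axis=0)
        np.testing.assert_allclose(out, matrix - baseline, atol=1e-12)

    def test_loudness_orders_silent_vs_loud_minutes(self):
        quiet = np.full(60 * 100, 0.001)
        loud = np.full(60 * 100, 0.5)
        rec = AudioRecording(np.concatenate([quiet, loud]), 100)
        loudness = minute_loudness(rec)
        assert loudness[0] < loudness[1]

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            calibrate_to_night(
                pd.DataFrame(rng.normal(size=(5, 2))), np.zeros(4)
            )
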