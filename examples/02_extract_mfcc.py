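"""Extract per-minute MFCC features from a synthetic night.

The chain: 25-ms Hamming frames at a 10-ms hop, 256-point FFT power
spectrum, 26 triangular Mel filters, natural log, cosine transform
keeping 13 static coefficients, then a per-coefficient mean over each
minute's frames.
"""

from snoregrade import SyntheticNightSpec, minute_mfcc, simulate_night

night = simulate_night(
    SyntheticNightSpec(duration_min=5, sample_rate=4000, target_ahi=24.0), seed=42
)
matrix = minute_mfcc(night.audio)

print(f"minute feature matrix: {matrix.shape[0]} minutes x {matrix.shape[1]} coefficients")
print(matrix.round(2).to_string())
print("apnea minutes:", [int(t) for t in matrix.index
                         if night.truth_record.labels[t - 1] == 1])
# Apnea minutes stand apart because silencing the snore changes the
# spectral envelope the cepstral coefficients summarize.
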