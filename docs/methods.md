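# Methods

This note records the model behind `snoregrade`, the parameter choices
that matter, what the synthetic data does and does not emulate, and the
design decisions taken where the problem left them open.

## Signal model and feature chain

The input is a mono PCM overnight recording `x(n)` (default 8 kHz, up
to 8 h). Analysis frames are 25 ms with a 10 ms hop and a Hamming
window — standard speech-processing defaults; the frame geometry is
configurable (`frame_length_s`, `hop_length_s`, `window_name`). Each
frame is zero-padded to `n_fft = 256` and transformed to a one-sided
power spectrum `|X(k)|²`, `k = 0..n_fft/2`; `n_fft` must be a power of
two (fast-transform requirement, enforced).

The Mel filter bank uses the HTK mapping `m = 2595·log10(1 + f/700)`
(the most widely used form; configurable in principle through
`hz_to_mel`/`mel_to_hz`). `M = 26` triangular filters span 0 Hz to
Nyquist, with `M + 2` anchor points equally spaced in Mel; filter
energies are `S_m = Σ_k |X(k)|²·H_m(k)`. Logs are natural with a floor
`ε = 1e-10` guarding `log(0)` on silent frames.

Cepstral coefficients follow
`C_l = Σ_{m=1..M} M_m·cos(π l (m − ½)/M)` for `l = 1..13` — a DCT-II
without orthonormal scaling and without the `l = 0` energy term. Two
consequences worth noting: a constant log-energy vector yields exactly
zero for every `l ≥ 1`, and a uniform gain change (which shifts all
`M_m` equally) cancels, so the 13 static coefficients describe spectral
*shape*, not loudness. No delta coefficients and no pre-emphasis are
computed; nothing downstream consumes them.

Frame vectors are aggregated per minute (frame assigned by its start
sample; `T = ceil(duration/60 s)` minutes, 1-based). The default
aggregation is the per-coefficient mean; `median` and a `(mean, std)`
concatenation are available via `minute_aggregation`. A minute
containing no frame start is zero-filled.

## Per-night calibration

Snore timbre (fundamental frequency, harmonic balance) varies strongly
between sleepers, and a classifier trained on a small cohort will see
held-out recordings whose timbre it never encountered. During
development this produced a concrete failure: one held-out night whose
snore fundamental lay outside the training nights' range was graded
wildly wrong because the trees routed its out-of-distribution minutes
arbitrarily.

The pipeline therefore references each minute's feature vector against
the same night's own snore baseline: the mean vector of the night's
`calibration_anchor_minutes = 3` loudest minutes (loudness = log mean
squared amplitude per minute) is subtracted from every row. The loudest
minutes are snore-dominated in any night that is not wall-to-wall
apnea, so features become "deviation from this sleeper's snoring",
which transfers across timbre. The step is on by default
(`night_calibration`) and uses only the night's own data, so it is
leakage-free at inference time.

Global standardization (zero mean, unit variance per column, population
standard deviation, unit divisor for constant columns) is then fitted
on training nights only and applied to held-out nights — held-out
columns need not have mean zero, by design.

## Sentence encoding

Each minute's (calibrated, standardized) coefficient vector is rendered
as `"[v1, v2, …, v13]"` with 4-decimal fixed precision — deterministic,
locale-free, and parseable back within `10^-precision`. One sentence
per minute is encoded independently, so fusion gets exactly one
semantic vector `s_t` per minute.

Two encoder backends share one interface:

- `DeterministicEncoder` (default): parse the numbers out of the
  sentence, multiply by a `(d_s, n)` matrix of unit normals drawn from
  `numpy.random.default_rng(seed)`, scale by `1/√n`, squash with
  `tanh`. Fully deterministic, no downloads, dimension-flexible
  (`encoder_dim`, default 16). Information preservation is tested: a
  classifier on the semantic features alone must beat chance at
  minute-level detection.
- `PretrainedBiomedicalEncoder`: wraps a local pretrained biomedical
  language model through the `transformers` stack, pooling the
  first-token hidden state by default (mean pooling optional), with an
  optional seeded linear down-projection to `d_s`. If its runtime
  dependencies or weights are missing it raises a clear error naming
  the deterministic fallback; it never substitutes silently. No
  fine-tuning is performed.

## Event labels: the 30-second rule

Annotated apnea intervals (half-open `[start_s, end_s)` seconds,
overlapping entries merged) become a binary minute record
`E = [e_1..e_T]`. Two readings of the rule are implemented:

- `event_duration` (default): `e_t = 1` iff some apnea event of total
  duration ≥ 30 s overlaps minute `t`. Chosen as default because under
  the alternative a 30–59 s event straddling a minute boundary could
  label no minute at all.
- `within_minute_overlap`: `e_t = 1` iff the total apnea overlap inside
  the minute (summed across events) is ≥ 30 s.

The threshold comparison is inclusive (≥ 30.000 s labels the minute).

## Classifier

Fusion concatenates `[s_t, C_t]` per minute (`inference_safe` mode). A
`literal` mode additionally appends the event label `e_t` itself
as a feature; since `e_t` is the prediction target this leaks the label
— the mode exists to demonstrate that leakage (a test shows training
accuracy ≈ 1 with pure-noise features) and is never the default.

The classifier is XGBoost with binary logistic loss minimizing the
usual regularized objective `Σ_i ℓ(y_i, ŷ_i) + Σ_k Ω(f_k)`. Default
hyperparameters are values tuned for this task by cross-validation:
learning rate 0.3, max depth 9, subsample 0.6, L2 = 10, L1 = 0.1,
column subsample 0.5, gamma 0.2; 100 boosting rounds (the package
default; cross-validation over a grid is provided). Training is seeded,
single-threaded, and records the per-round training log-loss. Scores
threshold at 0.5 by default. Cross-validation groups folds by night so
no sleeper contributes minutes to both sides of a fold.

## AHI and severity

`AHI = N/t` with `t` the recording duration in hours (no sleep staging
exists in the pipeline, so recorded time stands in for sleep time).
Two counting conventions for `N`: `positive_minutes` (default — the
natural aggregate of a per-minute classifier; per-patient AHI
estimates over 8-hour nights are then exact multiples of 1/8) and `contiguous_runs` (maximal runs of consecutive
positive minutes, the clinically conventional event count). Severity
bins: label 0 normal (< 5), 1 mild (5–<15), 2 moderate (15–<30),
3 severe (≥ 30); boundaries inclusive on the upper class.

Note the two conventions differ systematically: one apnea event of
duration `d ≥ 30 s` labels on average `1 + d/60` minutes, so
minute-count AHI runs higher than event-count AHI by a
duration-dependent factor. End-to-end evaluation therefore grades the
*reference* severity from the ground-truth minute record under the same
convention as the prediction; this isolates classifier error from the
convention offset.

Binary metrics implement the standard 2×2 formulas; a zero denominator
returns 0.0 with a warning, never NaN. MSE is the mean of squared
residuals and R² uses the standard denominator `Σ(y − ȳ)²`; an
`r2_mode="literal"` switch computes the alternative form with
denominator `Σ(ȳ − ŷ)²` for comparison. ROC is a threshold
sweep over distinct scores with trapezoidal AUC, which equals the
all-pairs rank statistic with ties counted half (tested exactly).
Feature interpretation is permutation importance — mean AUC drop over
seeded column shuffles.

## Synthetic nights

The generator emulates the one acoustic contrast the method relies on:
snoring versus apneic silence. Baseline audio is a harmonic stack
(5 harmonics, per-night fundamental uniform in 80–150 Hz) gated by a
per-breath envelope (4-s breath cycle, 40 % duty, squared half-sine),
over white noise (sd 0.01). Apnea events silence the snore component
while the noise floor remains; `round(target_ahi × hours)` events are
placed uniformly at random without overlap (minimum gap 5 s), durations
uniform in 20–90 s so that both sub-30-s events (which the rule leaves
unlabeled) and longer labeled events occur. Everything is reproducible
from `(spec, seed)`.

Not emulated: real snore timbre, gasps on breathing resumption, body
movement, room acoustics, co-sleepers, position changes, or any
physiological channel. Passing tests on this audio show the pipeline's
machinery is correct and that it recovers severity when the
snore/silence contrast is present; they bound nothing about clinical
recordings.

Cohorts draw per-night target AHIs from within-class ranges
(0.5–4, 6–13, 16–28, 30–40 events/h). The ranges sit strictly inside
the severity bins because the realized AHI is quantized — one event in
a 20-minute night is 3 events/h — and a target at a bin edge could
round into the neighboring class; the severe range is capped at 40 so
the drawn events always pack into the short profile. The short test
profile (20-minute nights at 4 kHz) exists so the full audio path runs
in seconds; full 8-h/8-kHz nights use the same code.

## Evaluation design

`run_pipeline` performs one seeded night-level 80/20 split (stratified
across severity classes by default, so the test set spans severities).
For cohort-level statistics the package uses `cross_fit_pipeline`:
nights are dealt into severity-stratified folds and each fold is graded
by a model fitted on the remaining nights — for six folds of twelve
nights, the same 10-train/2-test geometry as the single split, applied
to every night in turn. A two-night test set cannot support an
exact-match accuracy or a rank correlation (a single tied pair leaves
Spearman's rho undefined), so the headline recovery check —
twelve-night balanced cohort, severity accuracy above the 25 % chance
level, positive rank correlation between ground-truth and estimated
AHI — is computed over all twelve cross-fitted nights.

## Degenerate inputs and numerical choices

- Empty minutes (no frame start) are zero-filled and carry through.
- Constant feature columns standardize to zero (unit divisor).
- Single-class training labels, NaN features, mismatched feature
  columns, non-binary event records, and empty matrices all raise
  typed errors rather than propagating silently.
- Severity grading rejects negative AHI; `compute_ahi` rejects
  non-positive durations.
- Partial trailing hour segments and partial final minutes are kept
  (flagged), so nights shorter than 8 h remain gradable.
- All randomness flows from explicit integer seeds (`random_seed` in
  the run config; per-night seeds derived from a master seed).

## Known limitations

- Sleep time equals recording time; without sleep staging the AHI
  denominator overestimates sleep for restless sleepers.
- The minute-count convention inflates AHI relative to event counting
  by a duration-dependent factor (quantified above); comparisons
  against polysomnographic AHI should use `contiguous_runs` or a
  calibration.
- The deterministic encoder preserves information but adds no domain
  knowledge; any benefit a pretrained biomedical encoder would bring is
  untested here because no weights ship with the package.
- Hypopneas are not distinguished from apneas: labels are binary, as
  in the annotation scheme the pipeline targets.
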