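"""Generate one synthetic overnight recording with embedded apnea events.

Snoring is a breath-synchronous harmonic stack; an apnea event silences
it while the background-noise floor remains.  The generator also emits
the ground-truth annotations and the per-minute binary event record.
"""

from snoregrade import SyntheticNightSpec, simulate_night

spec = SyntheticNightSpec(duration_min=20, sample_rate=4000, target_ahi=24.0)
night = simulate_night(spec, seed=1)

print(f"audio: {night.audio.n_samples} samples at {night.audio.sample_rate} Hz "
      f"({night.audio.duration_seconds / 60:.0f} min)")
print(f"placed events (start_s, end_s, duration_s):")
for ev in night.events.apnea_events:
    print(f"  {ev.start_s:7.1f} {ev.end_s:7.1f} {ev.duration_s:5.1f}")
print(f"realized AHI (events/hour): {night.realized_ahi:.2f}")
print(f"truth record (1 = apnea minute): {night.truth_record.labels.tolist()}")
# Events shorter than 30 s exist but label no minute: that is the
# 30-second rule the pipeline must learn to reproduce acoustically.
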