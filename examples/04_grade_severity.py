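"""Count events, compute the AHI, and grade four-class OSAHS severity.

AHI = N / t (events per hour of sleep); bins: <5 normal, 5-<15 mild,
15-<30 moderate, >=30 severe.
"""

import numpy as np

from snoregrade import EventRecord, compute_ahi, count_events, grade_severity

# an 8-hour night with 44 apnea minutes scattered through it
labels = np.zeros(480, dtype=int)
labels[np.random.default_rng(0).choice(480, size=44, replace=False)] = 1
record = EventRecord(labels)

n = count_events(record, mode="positive_minutes")
result = compute_ahi(n, sleep_hours=8.0)
severity = grade_severity(result.ahi)
print(f"events: {n}, sleep: {result.sleep_hours} h, AHI: {result.ahi}")
print(f"severity: {severity.label} ({severity.name})")

for ahi in (2.125, 5.5, 18.0, 48.625):
    s = grade_severity(ahi)
    print(f"AHI {ahi:7.3f} -> label {s.label} ({s.name})")
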