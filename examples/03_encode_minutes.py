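"""Serialize a minute's MFCC vector as a sentence and encode it.

The deterministic encoder parses the numbers back out of the sentence
and applies a seeded random projection with a tanh squash — no model
download, identical output for identical input.
"""

import numpy as np

from snoregrade import DeterministicEncoder, encode, serialize_minute

coeffs = np.round(np.linspace(-2, 2, 13), 3)
sentence = serialize_minute(coeffs, precision=4)
print("sentence:", sentence.text)

encoder = DeterministicEncoder(d_s=8, seed=0)
vector = encode(sentence, encoder)
print("semantic vector (d_s=8):", np.round(vector, 4))
print("re-encoding identical:", np.array_equal(vector, encode(sentence, encoder)))
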