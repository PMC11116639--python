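"""Sentence serialization of per-minute MFCC vectors and semantic encoding.

Each minute's coefficient vector is rendered as a sentence-like string
("[1.0000, -2.5000, ...]") and passed through a text encoder to obtain a
fixed-dimension semantic vector.  Two backends exist:

* :class:`DeterministicEncoder` — the default.  Parses the numbers back
  out of the sentence, applies a seeded Gaussian random projection scaled
  by ``1/sqrt(n)``, and squashes with ``tanh``.  Fully deterministic,
  needs no network access or model weights, and preserves enough
  information for downstream event detection.
* :class:`PretrainedBiomedicalEncoder` — wraps a local pretrained
  biomedical language model (e.g. a PubMed-domain BERT) if its runtime
  stack and weights are present on disk; pooling is the first-token
  hidden state by default, mean pooling optionally.  If the backend
  cannot be initialized it raises :class:`EncoderUnavailableError`
  naming the fallback — it never silently substitutes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EncoderUnavailableError, SerializationError, ValidationError

__all__ = [
    "Sentence",
    "serialize_minute",
    "parse_sentence",
    "DeterministicEncoder",
    "PretrainedBiomedicalEncoder",
    "encode",
    "encode_night",
]


@dataclass(frozen=True)
class Sentence:
    """Sentence-like serialization of one minute's MFCC vector."""

    text: str
    minute_index: int = 0


def serialize_minute(coeffs, precision: int = 4, minute_index: int = 0) -> Sentence:
    """Render a coefficient vector as ``"[v1, v2, ...]"``.

    Fixed-precision decimal, leading sign kept, no locale separators;
    ``parse_sentence(serialize_minute(c).text)`` recovers ``c`` within
    ``10**-precision``.
    """
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.ndim != 1:
        raise SerializationError(f"expected a vector, got shape {coeffs.shape}")
    if not np.all(np.isfinite(coeffs)):
        raise SerializationError("cannot serialize non-finite coefficients")
    body = ", ".join(f"{v:.{precision}f}" for v in coeffs)
    return Sentence(text=f"[{body}]", minute_index=minute_index)


_NUMBER_RE = re.compile(r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")


def parse_sentence(text: str) -> np.ndarray:
    """Extract the numeric vector encoded by :func:`serialize_minute`."""
    values = _NUMBER_RE.findall(text)
    if not values:
        raise ValidationError(f"no numbers found in sentence {text!r}")
    return np.array([float(v) for v in values])


class DeterministicEncoder:
    """Seeded random-projection sentence encoder (download-free default).

    Construction of the projection, spelled out so it can be recomputed
    independently: ``rng = numpy.random.default_rng(seed)`` draws a
    ``(d_s, n)`` matrix ``P`` of unit normals, where ``n`` is the parsed
    vector length; the output is ``tanh(P @ v / sqrt(n))``.
    """

    name = "deterministic_fallback"

    def __init__(self, d_s: int = 16, seed: int = 0):
        if d_s < 1:
            raise ValidationError(f"d_s must be >= 1, got {d_s}")
        self.d_s = int(d_s)
        self.seed = int(seed)

    def encode_text(self, text: str) -> np.ndarray:
        vec = parse_sentence(text)
        rng = np.random.default_rng(self.seed)
        projection = rng.standard_normal((self.d_s, len(vec)))
        return np.tanh(projection @ vec / np.sqrt(len(vec)))


class PretrainedBiomedicalEncoder:
    """Pluggable pretrained sentence-encoder backend (local weights only).

    Requires the ``transformers``/``torch`` stack and a local model
    directory.  An optional seeded linear down-projection maps the
    model's hidden size to a configured ``d_s``.
    """

    name = "pretrained_biomedical_lm"

    def __init__(
        self,
        model_dir: str,
        pooling: str = "cls",
        d_s: int | None = None,
        seed: int = 0,
    ):
        if pooling not in ("cls", "mean"):
            raise ValidationError(f"pooling must be 'cls' or 'mean', got {pooling!r}")
        self.pooling = pooling
        self.seed = int(seed)
        try:
            from transformers import AutoModel, AutoTokenizer  # noqa: PLC0415
        except ImportError as exc:
            raise EncoderUnavailableError(
                "the pretrained encoder backend needs the 'transformers' and "
                "'torch' packages; use DeterministicEncoder for a "
                "download-free deterministic alternative"
            ) from exc
        try:
            self._tokenizer = AutoTokenizer.from_pretrained(model_dir)
            self._model = AutoModel.from_pretrained(model_dir)
        except Exception as exc:
            raise EncoderUnavailableError(
                f"no usable model weights at {model_dir!r}; use "
                "DeterministicEncoder for a download-free deterministic "
                "alternative"
            ) from exc
        hidden = int(self._model.config.hidden_size)
        self.d_s = int(d_s) if d_s is not None else hidden
        if self.d_s != hidden:
            rng = np.random.default_rng(self.seed)
            self._down = rng.standard_normal((self.d_s, hidden)) / np.sqrt(hidden)
        else:
            self._down = None

    def encode_text(self, text: str) -> np.ndarray:
        import torch  # noqa: PLC0415

        with torch.no_grad():
            tokens = self._tokenizer(text, return_tensors="pt", truncation=True)
            hidden = self._model(**tokens).last_hidden_state[0].numpy()
        pooled = hidden[0] if self.pooling == "cls" else hidden.mean(axis=0)
        if self._down is not None:
            pooled = self._down @ pooled
        return pooled.astype(np.float64)


def encode(sentence: Sentence, backend) -> np.ndarray:
    """Encode one sentence; identical input and backend give identical output."""
    return backend.encode_text(sentence.text)


_REANNOTATE = (SerializationError, ValidationError)


def encode_night(
    matrix: pd.DataFrame, backend, precision: int = 4
) -> pd.DataFrame:
    """Encode every minute of a feature matrix; row ``t`` is
    ``encode(serialize_minute(C_t))``.

    Minutes are encoded independently (no cross-minute state), so
    permuting input rows permutes output rows identically.
    """
    if len(matrix) == 0:
        raise ValidationError("cannot encode an empty feature matrix")
    rows = []
    for minute, row in zip(matrix.index, matrix.to_numpy(dtype=np.float64)):
        try:
            sent = serialize_minute(row, precision=precision, minute_index=int(minute))
            rows.append(encode(sent, backend))
        except _REANNOTATE as exc:
            raise type(exc)(f"minute {minute}: {exc}") from exc
    out = np.vstack(rows)
    columns = [f"sem_{i:02d}" for i in range(1, out.shape[1] + 1)]
    return pd.DataFrame(out, index=matrix.index, columns=columns)
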