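"""Exception hierarchy.

Every error raised by this package derives from :class:`SnoregradeError`
so callers can catch one type at the CLI boundary.
"""


class SnoregradeError(Exception):
    """Base class for all errors raised by snoregrade."""


class InputError(SnoregradeError):
    """A required input file is missing or unreadable."""


class UnsupportedFormatError(SnoregradeError):
    """An input file exists but is not in a supported format."""


class ValidationError(SnoregradeError):
    """Input content violates a documented contract (bad rows, bad labels)."""


class ConfigError(SnoregradeError):
    """A configuration value is out of its documented range."""


class FormatError(SnoregradeError):
    """A persisted artifact cannot be read back consistently."""


class TooShortError(SnoregradeError):
    """A recording is shorter than one analysis frame."""


class SerializationError(SnoregradeError):
    """A feature vector cannot be rendered as a sentence (e.g. NaN)."""


class EncoderUnavailableError(SnoregradeError):
    """The requested text-encoder backend cannot be initialized.

    Raised instead of silently substituting another backend; the message
    names the deterministic fallback as the download-free alternative.
    """


class DimensionError(SnoregradeError):
    """Two per-minute inputs disagree on the number of minutes T."""


class PackingError(SnoregradeError):
    """Requested apnea events cannot be placed inside the night."""
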