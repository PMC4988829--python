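"""Typed exceptions shared across the package."""


class TailTEError(Exception):
    """Base class for all package errors."""


class ConfigError(TailTEError):
    """Invalid configuration; message names the offending field."""


class SchemaError(TailTEError):
    """A table is missing required columns or contains malformed rows."""


class CorrelationError(TailTEError):
    """A correlation is undefined (too few points or zero variance)."""


class DegenerateIntervalError(TailTEError):
    """A genomic interval has its bounds on the wrong side of each other."""
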