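"""Exception types shared across the pipeline."""


class RollVectionError(Exception):
    """Base class for package-specific errors."""


class SchemaError(RollVectionError, ValueError):
    """A trial table, fit table or config violates the documented schema.

    The message names the offending rows/fields so that malformed logs can
    be fixed by hand.
    """


class StaircaseError(RollVectionError, RuntimeError):
    """Illegal operation on an adaptive track (e.g. stepping a finished one)."""


class UnsupportedDesignError(RollVectionError, ValueError):
    """The analysis was handed a design it does not support (e.g. an
    unbalanced repeated-measures table)."""


class UndefinedCorrelationError(RollVectionError, ValueError):
    """A correlation was requested for a zero-variance vector."""
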