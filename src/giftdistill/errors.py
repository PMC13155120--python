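"""Exception hierarchy shared across the package."""


class GiftDistillError(Exception):
    """Base class for all errors raised by giftdistill."""


class TableParseError(GiftDistillError):
    """A table file could not be parsed; the message names the offending row."""


class SchemaError(GiftDistillError):
    """A table violates its declared schema (missing column, bad dtype, duplicate key)."""


class InputError(GiftDistillError, ValueError):
    """An in-memory input violates a precondition of an operation."""


class DegenerateDataError(InputError):
    """The input is valid but degenerate for the requested computation (e.g. Rao Q = 0)."""


class StageError(GiftDistillError):
    """A pipeline stage failed; the message names the stage and the offending input."""
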