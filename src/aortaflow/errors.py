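"""Exception types."""


class AortaflowError(Exception):
    """Base class for all package errors."""


class ValidationError(AortaflowError, ValueError):
    """A physical or physiological invariant is violated."""


class SchemaError(AortaflowError, KeyError):
    """A tabular input is missing required rows/columns; the message names them."""


class ExtrapolationError(AortaflowError, ValueError):
    """A pressure was requested outside the sampled range of a record."""
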