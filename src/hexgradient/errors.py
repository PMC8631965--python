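"""Exception hierarchy shared across the package."""


class HexgradientError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HexgradientError):
    """A required column is missing or a dialect mapping is invalid."""


class ValidationError(HexgradientError):
    """Row-level content violates a documented invariant."""


class EmptyInputError(HexgradientError):
    """An input table contains no usable rows."""


class ParameterError(HexgradientError):
    """An operation was called with an out-of-range parameter."""


class UndefinedIndicatorError(HexgradientError):
    """The requested indicator is undefined for this slide (e.g. no
    tumor-stroma interface, no eligible tiles)."""
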