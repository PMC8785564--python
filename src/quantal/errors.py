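"""Exception hierarchy for quantal.

Every failure mode raised by the library derives from :class:`AssayError`,
so callers (and the CLI) can catch one base class.
"""


class AssayError(Exception):
    """Base class for all quantal errors."""


class SchemaError(AssayError):
    """Input table is missing a mandatory column or has no data rows."""


class ParseError(AssayError):
    """A cell could not be parsed; carries the 1-based file row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


class ValidationError(AssayError):
    """A parsed record violates an invariant (e.g. dead > total)."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


class DesignError(AssayError):
    """The experimental design cannot support the requested fit or test."""


class NonIdentifiableError(AssayError):
    """Model coefficients are not identifiable (e.g. complete separation)."""


class SaturatedControlError(AssayError):
    """Control mortality is 1; Abbott's correction is undefined."""


class UnboundedIntervalError(AssayError):
    """Fieller interval does not exist because Finney's g >= 1."""


class ConfigError(AssayError):
    """A simulation or run configuration field is invalid."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")


class HeterogeneityWarning(UserWarning):
    """Control replicates (or fit residuals) are more variable than binomial."""
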