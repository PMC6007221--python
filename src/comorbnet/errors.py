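"""Exception hierarchy shared across the package."""


class ComorbnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidQueryError(ComorbnetError):
    """A disease query or path query is malformed (e.g. no terms, no sources)."""


class UndefinedBackgroundError(ComorbnetError):
    """The background document set for relative-entropy scoring is empty."""


class InvalidInputError(ComorbnetError):
    """A numeric argument violates its domain (e.g. non-positive denominator)."""


class InsufficientDataError(ComorbnetError):
    """Fewer matched observations than the statistic requires."""


class BELParseError(ComorbnetError):
    """A line of BEL script could not be parsed.

    Carries the 1-based line number for error reporting.
    """

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class MissingCitationError(BELParseError):
    """A statement appeared before any ``SET Citation``."""


class UnknownLabelError(ComorbnetError, KeyError):
    """A subgraph label is not in the assembly's inventory."""

    def __init__(self, label: str, valid: list[str]):
        super().__init__(
            f"unknown subgraph label {label!r}; valid labels: {sorted(valid)}"
        )
        self.label = label
        self.valid = sorted(valid)


class SchemaValidationError(ComorbnetError):
    """A serialized assembly violates the node-link schema.

    ``field`` names the offending field.
    """

    def __init__(self, field: str, message: str):
        super().__init__(f"field {field!r}: {message}")
        self.field = field


class ConfigError(ComorbnetError):
    """A simulation configuration violates its invariants."""
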