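"""Exception types shared across the pipeline."""


class HerdspaceError(Exception):
    """Base class for package errors."""


class ConfigurationError(HerdspaceError):
    """Invalid simulation or run configuration."""


class DomainError(HerdspaceError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class FitError(HerdspaceError):
    """A model fit failed; carries the last iterate where available."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class SeparationError(FitError):
    """Complete separation in a logistic fit."""


class DegenerateTableError(HerdspaceError, ValueError):
    """A contingency table with a zero row or column margin."""


class ClassificationError(HerdspaceError, ValueError):
    """A progesterone series that cannot be classified (e.g. empty)."""


class SchemaError(HerdspaceError, ValueError):
    """A CSV input violating the expected schema; names file, row and column."""

    def __init__(self, message, file=None, row=None, column=None):
        super().__init__(message)
        self.file = file
        self.row = row
        self.column = column
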