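"""Exception hierarchy shared across the package."""


class RommaError(Exception):
    """Base class for all package-specific errors."""


class CohortFormatError(RommaError):
    """A cohort file is structurally unreadable (e.g. a mandatory column is absent)."""


class ValidationError(RommaError):
    """A field value violates its documented range or consistency rule.

    ``row`` carries the 0-based data-row index when the error arose while
    parsing a file, else ``None``.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class MissingInputError(RommaError):
    """A required variable for a Magee equation (or an operation) is absent."""


class EvaluationError(RommaError):
    """An evaluation step cannot proceed (missing ODX scores, empty groups...)."""
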