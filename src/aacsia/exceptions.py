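"""Exception hierarchy for data-contract failures.

Statistical non-significance is never an error; these exceptions mark
violated preconditions (bad schemas, missing measurements, degenerate
designs) so that pipeline stages fail loudly and name the offender.
"""


class AACSIAError(Exception):
    """Base class for all package errors."""


class SchemaError(AACSIAError):
    """Input table violates the expected schema (missing column, bad code,
    duplicate key, mismatched feature set)."""


class RowParseError(SchemaError):
    """A specific row could not be parsed; carries the row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class DomainError(AACSIAError):
    """A numeric argument is outside its physical domain (negative SD,
    non-positive distance, TDF <= 0, p outside [0, 1])."""


class IncompleteProfileError(AACSIAError):
    """A sample lacks a measurement required for the requested operation;
    names the missing amino acid."""


class EmptyResultError(AACSIAError):
    """A batch operation found zero qualifying records."""


class InsufficientDataError(AACSIAError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(AACSIAError):
    """The data admit no meaningful statistic (zero variance, coincident
    points, single point per group)."""


class ConfigError(AACSIAError):
    """An analysis or generator configuration is internally inconsistent."""
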