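"""Exception hierarchy for the pricing pipeline.

Grouping: :class:`InputError` covers everything a malformed cohort file or
record can trigger (exit code 2 in the CLI); :class:`AnalysisError` covers
conditions arising during computation on valid records.
"""


class VBPricingError(Exception):
    """Base class for all package errors."""


class InputError(VBPricingError):
    """Invalid user input (file, schema, or record contents)."""


class SchemaError(InputError):
    """The cohort CSV does not match the documented column schema."""


class ParseError(InputError):
    """A cell could not be parsed; carries the 1-based data row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class RecordValidationError(InputError):
    """A device record violates a domain invariant."""


class EmptyCohortError(InputError):
    """A cohort with no device rows cannot be evaluated."""


class AnalysisError(VBPricingError):
    """A computation could not be carried out on otherwise valid input."""


class UndefinedImprovementError(AnalysisError):
    """Relative improvement is undefined (comparator event rate is zero)."""


class NoComparatorPriceError(AnalysisError):
    """No comparator price is available (empty list, no override)."""


class InsufficientDataError(AnalysisError):
    """Too few priced devices for the concordance analysis (n < 3)."""


class ZeroVarianceError(AnalysisError):
    """Correlation/regression undefined because a coordinate is constant."""
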