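"""Exception hierarchy for table validation and estimation failures."""

from __future__ import annotations


class AscnaError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(AscnaError):
    """A required column is missing or a table is structurally unreadable."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = missing or []


class TableValidationError(AscnaError):
    """One or more rows violate a table invariant.

    ``rows`` holds the 0-based row indices (of the data rows, header
    excluded) that failed validation.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class EstimationError(AscnaError):
    """An estimator cannot produce a result from the given data."""

    def __init__(self, message: str, reason: str | None = None):
        super().__init__(message)
        self.reason = reason


class ShiftEstimationError(EstimationError):
    """No segment qualifies for the wild-type logR shift search."""


class AdmixtureEstimationError(EstimationError):
    """No clonal hemizygous-deletion candidate supports a DNA admixture call.

    Raised, rather than silently defaulting, because a copy-number-quiet
    genome and a fully admixed sample are indistinguishable from segmented
    coverage and SNP allelic fractions alone.
    """
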