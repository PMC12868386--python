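"""Named exception types raised by the pipeline.

Every validation failure carries enough context (file/table, row, field) to
locate the offending record in the input TSVs.
"""

from __future__ import annotations


class FecaldietError(Exception):
    """Base class for all package errors."""


class ValidationError(FecaldietError):
    """A table failed schema or referential-integrity validation."""

    def __init__(self, message: str, *, table: str | None = None,
                 row: int | None = None, field: str | None = None):
        self.table = table
        self.row = row
        self.field = field
        ctx = []
        if table is not None:
            ctx.append(f"table={table}")
        if row is not None:
            ctx.append(f"row={row}")
        if field is not None:
            ctx.append(f"field={field}")
        if ctx:
            message = f"{message} [{', '.join(ctx)}]"
        super().__init__(message)


class MissingColumnError(ValidationError):
    """A required column is absent from an input table."""


class InvalidValueError(ValidationError):
    """A cell holds a value outside its declared domain (bad enum, negative
    count, unparseable date, provenance score not in {0, 0.5, 1}, ...)."""


class DuplicateKeyError(ValidationError):
    """A primary-key constraint is violated (duplicate sample_id, duplicate
    (individual, date) collection, ...)."""


class DanglingReferenceError(ValidationError):
    """A foreign key (taxon_id, sample_id, mother_id) points at a record that
    does not exist or has the wrong attributes."""


class UnknownTaxonError(FecaldietError):
    """An operation was asked about a taxon the taxon table does not know."""


class UnknownSampleError(FecaldietError):
    """An operation was asked about a sample the metadata does not know."""


class UnscoredTaxonError(FecaldietError):
    """A provenance-weighted computation met a taxon without a score."""


class DegenerateInputError(FecaldietError):
    """The input is too small or too uniform for the requested statistic
    (empty RRA row, zero-variance similarity, < 2 samples per group, ...)."""


class ModelConvergenceError(FecaldietError):
    """A mixed-model fit failed to converge; diagnostics attached."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
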