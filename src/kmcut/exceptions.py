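"""Typed errors and warning categories raised across the pipeline.

Every error a user can trigger with a malformed table or a degenerate
analysis configuration has its own class, so callers (and the CLI) can
report the failing rule together with its coordinates.
"""

from __future__ import annotations


class KMCutError(Exception):
    """Base class for all kmcut errors."""


class UnparseableTable(KMCutError):
    """No delimiter yields a consistent column count across the header lines."""


class RoleRecognitionError(KMCutError):
    """A mandatory column role (time or event) could not be assigned."""

    def __init__(self, message: str, candidates: list[str] | None = None):
        super().__init__(message)
        self.candidates = candidates or []


class ValidationError(KMCutError):
    """A table violates one of the input-contract rules.

    Parameters
    ----------
    rule : short machine-readable rule name (e.g. ``too_many_columns``)
    row, column : 0-based coordinates of the offending cell where applicable
    """

    def __init__(self, rule: str, message: str, row: int | None = None,
                 column: int | None = None):
        super().__init__(message)
        self.rule = rule
        self.row = row
        self.column = column

    def to_dict(self) -> dict:
        return {"rule": self.rule, "row": self.row, "column": self.column,
                "message": str(self)}


class EmptyCohortError(KMCutError):
    """A filter selection or dichotomization left a cohort with no samples."""


class DegenerateGroupError(KMCutError):
    """A two-group test was requested but one group is empty."""


class NonConvergenceError(KMCutError):
    """Cox Newton-Raphson failed to converge (often monotone likelihood).

    ``direction`` holds the sign of the diverging coefficient(s) when the
    failure is a perfect separation of events (infinite hazard ratio).
    """

    def __init__(self, message: str, direction=None):
        super().__init__(message)
        self.direction = direction


class InsufficientEventsError(KMCutError):
    """Too few events for the requested computation."""


class ConstantVariableError(KMCutError):
    """A variable with zero variance cannot be dichotomized or regressed."""


class DegenerateTertilesError(KMCutError):
    """Heavy ties left a tertile empty during trichotomization."""


class ScanFailedError(KMCutError):
    """No cutoff candidate produced a usable two-cohort comparison."""


class InvalidWeightsError(KMCutError):
    """Signature weights are invalid (zero sum or negative entries)."""


class ZeroDenominatorError(KMCutError):
    """Ratio denominator contains zeros; offending sample ids attached."""

    def __init__(self, message: str, samples: list[str] | None = None):
        super().__init__(message)
        self.samples = samples or []


class CohortTooSmallError(KMCutError):
    """A stratified arm is smaller than the minimal analyzable size."""


class CollinearityError(KMCutError):
    """The multivariate design matrix is rank deficient."""

    def __init__(self, message: str, aliased: list[str] | None = None):
        super().__init__(message)
        self.aliased = aliased or []


class ConfigError(KMCutError):
    """Invalid analysis or simulation configuration."""


# ---------------------------------------------------------------------------
# warning categories

class KMCutWarning(UserWarning):
    """Base category for kmcut warnings."""


class NoEventsWarning(KMCutWarning):
    """All observations censored; the survival curve never drops."""


class SmallSampleWarning(KMCutWarning):
    """Cox model fitted on fewer than 40 samples; results are unreliable."""


class LowEventsWarning(KMCutWarning):
    """Fewer than 20% of samples have an event; curves barely drop."""


class AmbiguousCutoffWarning(KMCutWarning):
    """Several cutoffs tie for the minimal p; HR tie-break applied."""


class RecognitionWarning(KMCutWarning):
    """Column-role recognition resolved an ambiguity by fallback rules."""


class DataLossWarning(KMCutWarning):
    """Rows or columns were dropped/demoted during validation."""
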