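"""Exception and warning hierarchy for avrot.

All library errors derive from :class:`AvrotError` so callers (and the CLI)
can distinguish domain problems, fit failures and malformed input without
string matching.
"""

from __future__ import annotations


class AvrotError(Exception):
    """Base class for all avrot errors."""


class InvalidInputError(AvrotError, ValueError):
    """An argument violates a precondition (nonpositive ratio, bad grid...)."""


class SingularModelError(AvrotError, ArithmeticError):
    """The rational model's denominator vanishes at the evaluation point."""


class DomainError(AvrotError, ValueError):
    """A value lies outside the model's validity interval in strict mode."""


class NoRootError(AvrotError, ArithmeticError):
    """Bracketed root finding found no sign change for the requested value."""


class NonMonotoneError(AvrotError, ArithmeticError):
    """The model is not monotone over the inversion bracket (ambiguous root)."""


class DegenerateLandmarkError(AvrotError, ValueError):
    """Landmark geometry is degenerate (e.g. coincident body-edge points)."""


class InsufficientDataError(AvrotError, ValueError):
    """Too few data points for the requested fit or regression."""


class FitFailureError(AvrotError, RuntimeError):
    """Nonlinear least squares did not converge.

    Attributes
    ----------
    best_params : tuple or None
        Best iterate reached before failure, for diagnostics.
    """

    def __init__(self, message: str, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class TableRangeError(AvrotError, ValueError):
    """A lookup argument lies outside the table's covered range."""


class TableFormatError(AvrotError, ValueError):
    """A table or landmark CSV does not follow the expected dialect."""


class PipelineStageError(AvrotError, RuntimeError):
    """A refit-pipeline stage failed; names the stage and offending index."""

    def __init__(self, stage: str, key, original: Exception):
        self.stage = stage
        self.key = key
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed at {key!r}: {original}")


class PedicleOutsideBodyWarning(UserWarning):
    """Pedicle centre projects outside the vertebral-body segment (>10% of D)."""


class NonMonotoneDataWarning(UserWarning):
    """Column data are not strictly increasing in d with rotation."""


class RowIrregularityWarning(UserWarning):
    """Ratio-table row cells vary by more than 10% of the row mean."""


class FitInitWarning(UserWarning):
    """Linearized initialization was singular; fell back to unit start values."""
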