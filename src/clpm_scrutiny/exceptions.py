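"""Exception hierarchy for the package.

All errors raised by this package derive from :class:`ScrutinyError` so that
batch drivers can catch package-level failures without swallowing genuine
programming errors.
"""


class ScrutinyError(Exception):
    """Base class for all package errors."""


class SchemaError(ScrutinyError, ValueError):
    """A required field/column is missing or has the wrong type."""


class ValidationError(ScrutinyError, ValueError):
    """A value violates a domain invariant (e.g. a correlation outside [-1, 1])."""


class NotPositiveSemiDefiniteError(ValidationError):
    """A correlation/covariance matrix is not positive semidefinite."""

    def __init__(self, message: str, smallest_eigenvalue: float | None = None):
        super().__init__(message)
        self.smallest_eigenvalue = smallest_eigenvalue


class DegenerateDataError(ScrutinyError, ValueError):
    """Data are degenerate for the requested operation (zero variance, collinearity)."""


class ConvergenceError(ScrutinyError, RuntimeError):
    """The ML optimizer failed to reach the convergence criterion."""


class IdentificationError(ScrutinyError, RuntimeError):
    """The model is empirically under-identified (rank-deficient information)."""


class NumericalError(ScrutinyError, RuntimeError):
    """A numerical operation failed (singular matrix, root finding, ...)."""
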