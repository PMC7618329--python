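"""Exception hierarchy shared across the pipeline."""


class AqhimixError(Exception):
    """Base class for all package errors."""


class InvalidKnotsError(AqhimixError):
    """Spline knots unsorted, duplicated, or not enclosed by the boundary."""


class InvalidParameterError(AqhimixError, ValueError):
    """A numeric argument is outside its valid range."""


class DegenerateBasisError(AqhimixError):
    """Exposure series is constant (or otherwise spans no basis)."""


class SingularDesignError(AqhimixError):
    """Design matrix is rank deficient after dropping missing rows."""


class ConvergenceError(AqhimixError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class UnimputableError(AqhimixError):
    """Series has too few observed values to impute."""


class DataTooSparseError(AqhimixError):
    """Not enough complete days relative to the design width."""


class InsufficientStudiesError(AqhimixError):
    """Meta-analysis requires at least two studies."""


class UnstableBootstrapError(AqhimixError):
    """Too many bootstrap replicates failed to fit."""


class SchemaError(AqhimixError):
    """Input file or config does not match the expected schema."""
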