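"""Exception types shared across the analysis stages."""


class AviclimError(Exception):
    """Base class for all package-specific errors."""


class UndefinedCorrelationError(AviclimError):
    """A correlation was requested on an input with zero variance."""


class SingularDesignError(AviclimError):
    """The design matrix is rank deficient (perfectly collinear predictors)."""


class ConvergenceError(AviclimError):
    """Iteratively reweighted least squares failed to converge."""


class NoResultError(AviclimError):
    """Every candidate in a scan or selection was undefined."""
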