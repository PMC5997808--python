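"""Exception hierarchy shared across the package."""


class CritPowerError(Exception):
    """Base class for all package-specific errors."""


class InsufficientDataError(CritPowerError):
    """Fewer observations than the requested estimator needs."""


class SingularDesignError(CritPowerError):
    """Design matrix is rank-deficient (e.g. all trials share one duration)."""


class ValidationError(CritPowerError):
    """Input failed a structural or schema check."""


class ConvergenceError(CritPowerError):
    """Iterative fit failed to converge.

    Carries the best iterate found so the caller can inspect it.
    """

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class NoSolutionError(CritPowerError):
    """No parameter value in the admissible range satisfies the constraint."""


class InsufficientBaselineError(CritPowerError):
    """Passport baseline too small to condition on."""
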