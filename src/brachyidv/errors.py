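"""Exception types shared across the package."""


class BrachyIDVError(Exception):
    """Base class for package errors."""


class InvalidInputError(BrachyIDVError, ValueError):
    """An argument violates a documented precondition."""


class FormMismatchError(BrachyIDVError, ValueError):
    """A dose-response curve was evaluated with the wrong functional form."""


class NoSolutionError(BrachyIDVError, ValueError):
    """Moment matching has no feasible solution under the given constraints."""


class ConfigurationError(BrachyIDVError, ValueError):
    """A configuration object is internally inconsistent."""


class SeparationError(BrachyIDVError, RuntimeError):
    """Logistic MLE is unbounded: outcomes are (quasi-)completely separated."""


class ConvergenceError(BrachyIDVError, RuntimeError):
    """An iterative fit did not converge; diagnostics in ``details``."""

    def __init__(self, message: str, details=None):
        super().__init__(message)
        self.details = details


class ContractError(BrachyIDVError, ValueError):
    """An operation was called on an object excluded by the analysis rules."""


class GridError(BrachyIDVError, ValueError):
    """A dose lies outside, or a level is not bracketed by, the dose grid."""
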