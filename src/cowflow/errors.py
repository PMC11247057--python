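"""Exception hierarchy shared across the package."""


class CowflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CowflowError, ValueError):
    """A caller supplied data violating a documented precondition."""


class ValidationError(CowflowError, ValueError):
    """A composite structure (network, mesh, config) failed validation."""


class ConfigurationError(CowflowError, ValueError):
    """Inconsistent or infeasible configuration values."""


class UnphysicalStateError(CowflowError, RuntimeError):
    """The solver reached a state outside the model's validity (e.g. A <= 0)."""


class ConvergenceError(CowflowError, RuntimeError):
    """The nonlinear solve failed to reach tolerance."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])
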