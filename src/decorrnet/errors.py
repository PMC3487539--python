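"""Exception types shared across the package."""


class DecorrnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DecorrnetError, ValueError):
    """Invalid model, network or run configuration."""


class InputError(DecorrnetError, ValueError):
    """Invalid data passed to an operation (spike data, surrogate modes, ...)."""


class NumericalError(DecorrnetError, ArithmeticError):
    """Numerical failure during simulation or solving (NaN, divergence)."""


class StabilityError(DecorrnetError, ValueError):
    """The linearized network model is outside its stability region."""


class ConvergenceError(DecorrnetError, ArithmeticError):
    """An iterative scheme failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
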