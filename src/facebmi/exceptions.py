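"""Exception hierarchy shared across the package."""


class FaceBMIError(Exception):
    """Base class for all package errors."""


class FormatError(FaceBMIError, ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(FaceBMIError, ValueError):
    """An input violates a documented precondition."""


class DegenerateInputError(FaceBMIError, ValueError):
    """Geometrically or numerically degenerate input (coincident pupils,
    zero variance, collinear points, zero-area triangle, ...)."""


class ConfigurationError(FaceBMIError, ValueError):
    """An invalid or inconsistent configuration value."""


class ConvergenceError(FaceBMIError, RuntimeError):
    """An iterative solver failed to converge within its budget."""
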