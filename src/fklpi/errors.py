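"""Exception hierarchy shared across the package."""


class FKLPIError(Exception):
    """Base class for all package-specific errors."""


class UnknownModelError(FKLPIError):
    """Requested potential model name is not registered."""


class InvalidParameterError(FKLPIError):
    """A model or run parameter is missing, non-finite or out of range."""


class SingularConfigurationError(FKLPIError):
    """A configuration (e.g. overlapping particles) produced a non-finite energy."""


class ContinuationRangeError(FKLPIError):
    """The imaginary-frequency analytic continuation left its validity window
    (hbar*|Omega|*beta >= 2*pi for the smearing width / centroid potential)."""


class BarrierValidityError(FKLPIError):
    """Phase-space sampling at an imaginary effective frequency violates the
    bound hbar*|Omega|*beta < pi, or a barrier mode reached a positive-branch
    code path."""


class ConvergenceError(FKLPIError):
    """An iterative solve failed to converge within max_iter."""


class EstimatorError(FKLPIError):
    """Unsupported operator/flavor combination or estimator misuse."""


class GridError(FKLPIError):
    """Non-uniform/incommensurate grids, unconverged grid solutions."""


class ConfigError(FKLPIError):
    """Invalid run configuration (unknown keys, missing seed, ...)."""
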