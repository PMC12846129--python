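"""Exception taxonomy shared across the package."""


class GradeFuseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GradeFuseError):
    """Invalid configuration value (shapes, spacings, probabilities, ...)."""


class InputError(GradeFuseError):
    """Malformed runtime input (shape mismatch, empty sets, bad widths)."""


class DegenerateStatisticsError(GradeFuseError):
    """Statistics cannot be formed (constant region, zero variance)."""


class UndefinedMetricError(GradeFuseError):
    """A metric is undefined for the given data (single class, no pairs)."""


class UnfittableVariableError(GradeFuseError):
    """A clinical variable has no observed training values to fit on."""


class InsufficientNeighborsError(GradeFuseError):
    """A minority cell is too small for neighbor-based oversampling."""
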