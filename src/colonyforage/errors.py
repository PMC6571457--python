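"""Exception types shared across the package."""


class ColonyForageError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(ColonyForageError, ValueError):
    """A world configuration violates its invariants."""


class InvalidParamsError(ColonyForageError, ValueError):
    """Movement-model parameters are outside their admissible domain."""


class InvalidDistanceError(ColonyForageError, ValueError):
    """A distance matrix is asymmetric, has a non-zero diagonal, or is otherwise malformed."""


class DegenerateColumnError(ColonyForageError, ValueError):
    """An environmental column has zero variance and cannot be standardized."""


class DegenerateGroupError(ColonyForageError, ValueError):
    """A group is too small for the requested dispersion test."""


class EmptyDomainError(ColonyForageError, ValueError):
    """No grid cells fall inside the requested foraging radius."""


class UndefinedMetricError(ColonyForageError, ValueError):
    """A trip metric is requested for a trip that cannot support it."""


class SeparationError(ColonyForageError, ValueError):
    """A proportion response is degenerate (all zeros or all ones)."""


class GridOverflowError(ColonyForageError, ValueError):
    """A kernel-density grid would exceed the configured maximum extent."""
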