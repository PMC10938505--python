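"""Exception hierarchy."""


class RnaGrowError(Exception):
    """Base class for all package errors."""


class InputError(RnaGrowError, ValueError):
    """Invalid arguments or malformed input data."""


class GeometryError(RnaGrowError):
    """Degenerate geometry (collinear point sets, undefined frames)."""


class SequenceMismatchError(InputError):
    """Fragments are incompatible at their overlap."""


class ValidationError(RnaGrowError):
    """A structure or library failed validation."""


class PlanningError(InputError):
    """No fragment tiling reaches the requested target sequence."""


class GrowthFailureError(RnaGrowError):
    """Chain growth exhausted its attempt budget at some tree node."""

    def __init__(self, message, level=None, acceptance_rate=None):
        super().__init__(message)
        self.level = level
        self.acceptance_rate = acceptance_rate


class ConvergenceError(RnaGrowError):
    """An iterative optimization failed to converge."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
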