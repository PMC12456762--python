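"""Exception hierarchy shared across the package."""


class MaskshakerError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MaskshakerError):
    """An on-disk artifact does not conform to the expected format."""


class ValidationError(MaskshakerError, ValueError):
    """Inputs violate an operation's preconditions."""


class GenerationError(MaskshakerError):
    """Synthetic-tissue generation could not satisfy the requested spec."""

    def __init__(self, message: str, achieved_count: int | None = None):
        super().__init__(message)
        self.achieved_count = achieved_count


class CalibrationError(MaskshakerError):
    """No candidate parameter set reached the target segmentation quality."""

    def __init__(self, message: str, closest_f1: float | None = None):
        super().__init__(message)
        self.closest_f1 = closest_f1
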