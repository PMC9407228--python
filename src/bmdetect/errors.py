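"""Exception types shared across the detection pipeline."""


class BMDetectError(Exception):
    """Base class for package-specific failures."""


class FormatError(BMDetectError):
    """A file could not be parsed as the expected format."""


class DimensionError(BMDetectError, ValueError):
    """An array has a shape the operation cannot work with."""


class PlacementError(BMDetectError):
    """Lesion placement could not satisfy its geometric constraints."""


class PoolExhaustedError(BMDetectError):
    """A sampling pool required by the batch composition is empty."""


class InfeasibleSensitivityError(BMDetectError):
    """Requested sensitivity exceeds what the model can reach on the data.

    Carries the achievable peak so callers can back off.
    """

    def __init__(self, requested: float, peak: float):
        self.requested = requested
        self.peak = peak
        super().__init__(
            f"target sensitivity {requested:.3f} exceeds achievable peak {peak:.3f}"
        )


class UndefinedRateError(BMDetectError, ZeroDivisionError):
    """A rate (capture rate, sensitivity) is undefined because its denominator is empty."""
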