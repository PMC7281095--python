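"""Exception hierarchy for the co-flow rheometry toolchain."""


class CoflowError(Exception):
    """Base class for all package-specific errors."""


class ValidityRangeError(CoflowError, ValueError):
    """A quantity lies outside the fitted validity interval (e.g. the
    correction-factor polynomial, calibrated only on 0.1 < alpha < 0.9)."""


class IntegrationDomainError(CoflowError, RuntimeError):
    """The nonlinear circuit ODE drove the interface fraction out of the
    correction-factor validity interval during integration."""

    def __init__(self, message: str, time_s: float | None = None):
        super().__init__(message)
        self.time_s = time_s


class LowContrastError(CoflowError, ValueError):
    """The image ROI is not bimodal enough for Otsu thresholding."""


class GeometryDetectionError(CoflowError, ValueError):
    """Channel walls could not be located in the image."""


class DegenerateFitError(CoflowError, ValueError):
    """The transient amplitude is too small for an exponential fit."""


class FitError(CoflowError, RuntimeError):
    """Nonlinear regression failed to converge."""


class EmptyResultError(CoflowError, ValueError):
    """All samples were excluded by a validity filter."""
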