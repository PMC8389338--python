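"""Exception types shared across the package."""


class DimensionError(ValueError):
    """An image / matrix dimension argument is invalid."""


class InsufficientSamplesError(ValueError):
    """Too few samples (images, time steps, ranks) for the requested operation."""


class NormalizationError(ValueError):
    """Pixel values fall outside the required [0, 1] range."""


class InvalidClassCountError(ValueError):
    """Fewer than two classes requested for a labeled generator or classifier."""


class DegenerateMatrixError(RuntimeError):
    """A sampled reservoir matrix is identically zero; retry with another seed."""


class DegeneratePerturbationError(RuntimeError):
    """Trajectory separation underflowed to exactly zero during MLE estimation."""


class FitError(RuntimeError):
    """A power-law fit could not be carried out on the requested range."""


class CalibrationError(RuntimeError):
    """Edge-of-chaos calibration could not reach the target MLE window."""

    def __init__(self, message, curve=None):
        super().__init__(message)
        #: list of (parameter value, measured MLE) pairs scanned before failing
        self.curve = curve or []
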