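"""Exception types shared across the measurement pipeline."""


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class DegenerateConfigurationError(ValidationError):
    """Landmark configuration has fewer than 3 usable points or is collinear."""


class CorrespondenceError(ValidationError):
    """Landmark label sets cannot be matched across time points."""


class EmptyROIError(ValidationError):
    """Cutting plane does not intersect the mesh / leaves no ROI piece."""


class ClosureError(ValidationError):
    """A boundary loop could not be capped into a watertight surface."""

    def __init__(self, message, loops=None):
        super().__init__(message)
        # diagnostic: list of vertex-index loops that failed to close
        self.loops = loops or []


class DetectionError(ValidationError):
    """No suitable calibration object found in a radiograph."""


class InsufficientReplicatesError(ValidationError):
    """Measurement-uncertainty computation needs at least two repeats."""
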