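"""Exception hierarchy for dloplan."""


class DloplanError(Exception):
    """Base class for all dloplan errors."""


class InvalidGeometryError(DloplanError):
    """A geometric construction is degenerate (zero-length direction,
    line parallel to a required crossing, landmark invariant violated)."""


class NoIntersectionError(InvalidGeometryError):
    """Two lines are parallel within tolerance and do not intersect."""


class UnsupportedDeformityError(DloplanError):
    """The limb is valgus (or already past the target); the planning
    method is validated for varus limbs only."""


class OutOfRangeError(DloplanError):
    """A requested offset falls outside a cortical segment's extent."""


class CalibrationError(DloplanError):
    """Calibration scale missing or non-positive."""


class GenerationError(DloplanError):
    """Synthetic-limb generation failed (inconsistent spec or
    resampling exhaustion)."""


class ConvergenceError(DloplanError):
    """The virtual-segmentation solver failed to converge."""

    def __init__(self, message: str, residuals=None, iterations: int = 0):
        super().__init__(message)
        self.residuals = residuals
        self.iterations = iterations


class DegenerateDataError(DloplanError):
    """Statistical input has no usable variance or violates table shape."""


class LandmarkValidationError(DloplanError):
    """A landmark file failed schema validation."""
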