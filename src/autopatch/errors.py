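"""Exception hierarchy for the autopatch package."""


class AutopatchError(Exception):
    """Base class for all package-specific errors."""


class PlacementError(AutopatchError):
    """Raised when phantom cells cannot be placed at the requested density."""


class BoundsError(AutopatchError):
    """Raised when a model or move falls outside the image volume."""


class DetectionFailureError(AutopatchError):
    """Raised when no pipette-like structure can be found in a stack."""


class RefinementError(AutopatchError):
    """Raised when model refinement terminates worse than its starting point."""


class DegenerateCalibrationError(AutopatchError):
    """Raised when calibration moves do not span three dimensions."""


class TrackingLostError(AutopatchError):
    """Raised when all tracked features have been lost."""


class PlanningError(AutopatchError):
    """Raised when a pipette trajectory cannot be planned."""


class TravelLimitError(AutopatchError):
    """Raised when a commanded manipulator move exceeds the travel range."""


class ConfigurationError(AutopatchError):
    """Raised for missing or inconsistent run configuration."""


class StateError(AutopatchError):
    """Raised when an operation is invoked in the wrong controller phase."""


class AnnotationError(AutopatchError):
    """Raised for malformed annotation records; carries per-record details."""

    def __init__(self, message, record_errors=None):
        super().__init__(message)
        self.record_errors = list(record_errors or [])
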