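"""Exception hierarchy for tdcsfem.

All package errors derive from :class:`TdcsFemError` so callers can catch
one base class at pipeline level while tests discriminate precisely.
"""


class TdcsFemError(Exception):
    """Base class for all tdcsfem errors."""


class InvalidGeometryError(TdcsFemError):
    """Mesh or shell geometry violates a structural precondition."""


class ResolutionError(TdcsFemError):
    """Mesh resolution too coarse to resolve a geometric feature."""


class OutOfDomainError(TdcsFemError):
    """A point lies outside the head domain."""


class ConfigError(TdcsFemError):
    """Invalid or incomplete run configuration."""


class FiducialError(TdcsFemError):
    """A required anatomical fiducial is missing or invalid."""


class FormatError(TdcsFemError):
    """Unsupported or corrupt mesh/field file."""


class MontageError(TdcsFemError):
    """Electrode montage violates a structural constraint."""


class PlacementError(TdcsFemError):
    """Electrode or grid reference cannot be placed on the skin surface."""


class ConvergenceError(TdcsFemError):
    """Iterative solver failed to reach the requested residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ROIError(TdcsFemError):
    """Region of interest contains no qualifying elements."""


class SearchError(TdcsFemError):
    """Montage search has no admissible candidate pair."""


class DegenerateDataError(TdcsFemError):
    """Statistical routine received degenerate data (constant, empty...)."""


class ShapeError(TdcsFemError):
    """Array arguments have inconsistent shapes."""
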