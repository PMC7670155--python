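"""Exception types shared across the package."""


class AcromorphError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometryError(AcromorphError, ValueError):
    """Raised when input points are collinear/coincident or a fit is ill-posed."""


class InfeasibleGeometryError(AcromorphError, ValueError):
    """Raised when a synthetic shoulder specification cannot be realised."""


class SideError(AcromorphError, ValueError):
    """Raised when a shoulder side is unknown or inconsistent."""


class FrameOrientationError(AcromorphError, ValueError):
    """Raised when landmark geometry contradicts the frame orientation rules."""


class MissingLandmarkError(AcromorphError, KeyError):
    """Raised when a required landmark is absent from an annotation file."""


class MeshFormatError(AcromorphError, ValueError):
    """Raised when a mesh file cannot be parsed."""


class StatisticsError(AcromorphError, ValueError):
    """Raised when a statistical routine receives degenerate input."""
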