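"""Exception hierarchy for sdtrack."""


class SDTrackError(Exception):
    """Base class for all sdtrack errors."""


class MeshParseError(SDTrackError):
    """A surface file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" in {path}"
        if line is not None:
            loc += f" at line {line}"
        super().__init__(message + loc)


class MeshValidationError(SDTrackError):
    """A mesh violates a structural invariant (index range, manifoldness, ...)."""


class InsufficientMarginError(SDTrackError):
    """An electrode lies too close to the parent mesh boundary to cut a patch."""


class SmoothingDivergenceError(SDTrackError):
    """Edge-length-preserving smoothing moved an edge beyond the safety bound."""


class DegenerateSnapError(SDTrackError):
    """Two electrode centroids snapped to the same mesh vertex."""


class InsufficientRoomError(SDTrackError):
    """A synthetic electrode strip would run off the mesh."""


class EventSchemaError(SDTrackError):
    """An SD event table violates the documented schema."""


class SearchError(SDTrackError):
    """Trajectory search was asked for something it cannot provide."""
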