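"""Exception types shared across the pipeline stages."""


class PentrackError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(PentrackError):
    """Raised when a pen-geometry configuration is inconsistent."""


class UnknownLabelError(PentrackError, KeyError):
    """Raised when an antenna or zone label does not exist in the geometry."""


class EmptyTrackError(PentrackError):
    """Raised when a track is requested for a bird with no usable fixes."""


class SpanError(PentrackError):
    """Raised when two tracks do not share the time span an operation needs."""


class SchemaError(PentrackError):
    """Raised when an input table does not match the expected column schema."""
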