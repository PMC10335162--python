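"""Exception hierarchy shared by all facemetrics modules."""


class FacemetricsError(Exception):
    """Base class for all package-specific errors."""


class ParseError(FacemetricsError):
    """A landmark or cohort file could not be parsed; message names the line."""


class SchemaError(FacemetricsError):
    """Input violates the landmark/record schema (duplicates, missing names)."""


class GeometryError(FacemetricsError):
    """Landmark configuration is geometrically degenerate or inconsistent."""


class ParameterError(FacemetricsError):
    """A numeric parameter is out of its valid domain."""


class SegmentationError(FacemetricsError):
    """Iris segmentation failed (no foreground, collapsed contour, ...)."""
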