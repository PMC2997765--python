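"""Exception hierarchy for the lenscount pipeline."""


class LensCountError(Exception):
    """Base class for all package errors."""


class ParameterError(LensCountError, ValueError):
    """Invalid parameter value (angles, counts, fractions, sizes)."""


class VisibilityError(LensCountError):
    """Point lies on the hemisphere not visible in the requested projection."""


class GeometryError(LensCountError):
    """Degenerate geometric construction (coincident points, out-of-disk y, ...)."""


class FitError(LensCountError):
    """Circle or sphere fit cannot be performed (too few / collinear points)."""


class MetadataError(LensCountError):
    """Image is missing required physical metadata (pixel size, origin)."""


class DetectionError(LensCountError):
    """Detection produced no usable nuclei where the pipeline requires them."""


class RegistrationError(LensCountError):
    """No view rotation aligns the two EdU point patterns with >= 3 inliers."""
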