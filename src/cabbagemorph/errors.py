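"""Exception hierarchy shared across the pipeline."""


class CabbageMorphError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CabbageMorphError):
    """A file does not follow the declared dialect (wrong dtype, channels, sign)."""


class MappingError(CabbageMorphError):
    """An annotation category cannot be mapped to a known class."""


class DegenerateCloudError(CabbageMorphError):
    """A point cloud has too few points to support the requested operation."""


class DegenerateGeometryError(CabbageMorphError):
    """Sampled or supplied geometry is rank-deficient (collinear points, parallel planes)."""


class DegenerateMaskError(CabbageMorphError):
    """A mask has no foreground pixels."""


class InsufficientPlanesError(CabbageMorphError):
    """Fewer than three usable leaf planes; no triple intersection exists."""


class NoSupportError(CabbageMorphError):
    """No intersection point survived filtering; the attachment point is undefined."""


class MissingDepthError(CabbageMorphError):
    """No valid depth pixel inside the mask of interest."""


class PairingError(CabbageMorphError):
    """Two paired sequences differ in length."""


class InsufficientDataError(CabbageMorphError):
    """Too few values for the requested statistic."""


class EmptyPlantError(CabbageMorphError):
    """A plant with zero measured leaves cannot produce area totals."""


class InvalidMeasureError(CabbageMorphError):
    """A measured quantity violates its physical domain (non-positive length)."""


class LayoutError(CabbageMorphError):
    """Synthetic plants are placed closer than the minimum stem spacing."""
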