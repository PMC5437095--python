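"""Typed exceptions raised across the package."""


class BpequantError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(BpequantError):
    """Phantom geometry does not fit inside the requested grid."""


class GridMismatchError(BpequantError):
    """Two volumes do not share grid shape and voxel spacing."""


class SegmentationError(BpequantError):
    """Breast segmentation failed (e.g. no foreground at all)."""


class DegenerateClusteringError(SegmentationError):
    """Intensity clustering inside a mask found no class structure."""


class CohortValidationError(BpequantError):
    """A cohort table violates the documented schema or pairing rules."""


class ConvergenceError(BpequantError):
    """An iterative fit failed to converge."""
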