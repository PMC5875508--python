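"""Exception hierarchy for the segmentation pipeline.

Per-organ failures raise subclasses of :class:`SegmentationError` so the
pipeline can downgrade them to report entries instead of aborting a run.
"""


class SegmentationError(Exception):
    """Base class for recoverable per-structure failures."""


class GeometryError(SegmentationError):
    """Invalid or non-invertible voxel-grid geometry."""


class GridMismatchError(SegmentationError):
    """Operands live on different voxel grids."""


class MetricDegenerateError(SegmentationError):
    """Too few valid samples to evaluate the image-match metric."""


class MaskCoverageError(SegmentationError):
    """No metric samples map inside the organ mask at some stage."""


class FusionFailureError(SegmentationError):
    """Probability-map thresholding produced an empty organ; the organ
    needs manual segmentation."""


class DegenerateHistogramError(SegmentationError):
    """In-mask intensity histogram has fewer distinct values than the
    requested number of classes."""


class EmptyInterfaceError(SegmentationError):
    """A level-set field lost its zero crossing (all one sign)."""


class UndefinedMetricError(SegmentationError):
    """Overlap metric undefined (e.g. both masks empty)."""


class PhantomSpecError(ValueError):
    """Synthetic phantom specification violates its invariants."""


class ConfigurationError(ValueError):
    """Invalid pipeline configuration (e.g. fewer than two atlases)."""
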