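"""Exception hierarchy for emphkit.

Every contract violation raises a subclass of :class:`EmphkitError`, so
callers can catch pipeline failures without masking programming errors.
"""


class EmphkitError(Exception):
    """Base class for all emphkit-specific failures."""


class SeriesError(EmphkitError):
    """DICOM series catalog or geometry problems (empty catalog,
    inhomogeneous series, degenerate slice geometry)."""


class SidecarError(EmphkitError):
    """Volume persistence problems: orphan array files, invalid sidecars."""


class SegmentationError(EmphkitError):
    """Lung segmentation produced an empty mask or an external mask
    cannot be reconciled with the volume grid."""


class EmptyMaskError(EmphkitError):
    """A densitometry operation received a mask with no lung voxels."""


class BackendError(EmphkitError):
    """Unknown or unavailable embedding backend, or missing weights."""


class DegenerateDataError(EmphkitError):
    """Inputs make the requested statistic undefined: a single-class
    cohort, an unbalanced subset request, a metric without both classes."""


class BootstrapError(EmphkitError):
    """Percentile bootstrap could not draw enough valid resamples."""


class PhantomError(EmphkitError):
    """Synthetic phantom target unreachable or spec invalid."""
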