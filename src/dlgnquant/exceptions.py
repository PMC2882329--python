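"""Exception hierarchy.

Every rejected input raises a distinct subclass so callers (and the
pipeline's exclusion accounting) can tell failure modes apart.
"""


class DlgnQuantError(ValueError):
    """Base class for all domain errors."""


class ShapeMismatchError(DlgnQuantError):
    """Image, mask and annotation grids must share one shape."""


class EmptyMaskError(DlgnQuantError):
    """The dLGN mask contains no pixels."""


class MissingLandmarkError(DlgnQuantError):
    """A required landmark key is absent from the annotation file."""


class LandmarkError(DlgnQuantError):
    """A landmark does not lie where its contract requires (e.g. off the mask boundary)."""


class BackgroundPlacementError(DlgnQuantError):
    """The background-reference region is missing, the wrong size, out of
    bounds, or overlaps the dLGN."""


class InsufficientSectionsError(DlgnQuantError):
    """Too few serial sections for the requested construction."""


class ThresholdError(DlgnQuantError):
    """A threshold (or the reference intensity it derives from) is non-positive."""


class MonocularRegionError(DlgnQuantError):
    """The monocular-segment annotation is missing or too small."""


class StripError(DlgnQuantError):
    """The profile strip does not fit in the image or is shorter than the
    normalization segment."""


class EmptyPatchSetError(DlgnQuantError):
    """An axis length was requested but no patch survived the size filter."""


class DegenerateTangentError(DlgnQuantError):
    """The local outer-boundary tangent could not be estimated."""


class PhantomError(DlgnQuantError):
    """A phantom specification is invalid or geometrically infeasible."""


class StatsError(DlgnQuantError):
    """A statistical routine received groups it cannot handle."""
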