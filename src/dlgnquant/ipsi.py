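"""Ipsilateral projection quantification.

The ipsilateral territory is thresholded at a fraction ``alpha`` of the
maximum background-subtracted signal over five consecutive sections centred
on the section with the largest dLGN area. Supra-threshold area (strictly
greater than the threshold) inside the dLGN gives the CTB-positive area and
its fraction of the dLGN; size-filtered 8-connected components of the
supra-threshold mask (> 150 px) are the ipsilateral patches used for the
axis-length measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import InsufficientSectionsError, ThresholdError
from .section import SectionImage, SectionSeries, dlgn_area

#: Components with pixel count <= this cutoff are removed ("small CTB-positive
#: areas"); retained components are the ipsilateral patches.
MIN_PATCH_PIXELS = 150

#: Default proportionality coefficient of the ipsilateral threshold.
DEFAULT_ALPHA = 0.3

_EIGHT = np.ones((3, 3), dtype=bool)


def series_max_intensity(series: SectionSeries, center_index: int) -> float:
    """Maximum signal over five consecutive sections, the third of which is
    ``center_index`` (the largest-area section), restricted to each
    section's dLGN mask.

    Sections are expected to be background-subtracted already.
    """
    lo, hi = center_index - 2, center_index + 2
    if lo < 0 or hi >= len(series):
        raise InsufficientSectionsError(
            f"five consecutive sections around index {center_index} do not exist"
        )
    return float(
        max(
            series[i].intensity[series[i].dlgn_mask].max()
            for i in range(lo, hi + 1)
        )
    )


def ipsi_threshold(ref_max: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Ipsilateral threshold: ``alpha`` times the five-section maximum."""
    if ref_max <= 0:
        raise ThresholdError("reference maximum must be positive to set a threshold")
    if not 0 < alpha < 1:
        raise ThresholdError("alpha must lie strictly between 0 and 1")
    return float(alpha * ref_max)


def ctb_positive_area(section: SectionImage, threshold: float) -> tuple[float, float]:
    """CTB-positive area (um^2) and its percentage of the dLGN area.

    A pixel counts when its (background-subtracted) intensity is strictly
    greater than ``threshold`` and it lies inside the dLGN mask.
    """
    if threshold <= 0:
        raise ThresholdError("threshold must be positive")
    positive = (section.intensity > threshold) & section.dlgn_mask
    area = float(positive.sum()) * section.pixel_area_um2
    fraction = 100.0 * area / dlgn_area(section)
    return area, fraction


def supra_threshold_mask(section: SectionImage, threshold: float) -> np.ndarray:
    """Binary mask of supra-threshold pixels inside the dLGN."""
    if threshold <= 0:
        raise ThresholdError("threshold must be positive")
    return (section.intensity > threshold) & section.dlgn_mask


@dataclass(eq=False)
class Patch:
    """One retained connected component of the supra-threshold mask."""

    pixels: np.ndarray  # (n, 2) int array of (row, col)

    @property
    def size(self) -> int:
        return len(self.pixels)

    @property
    def centroid(self) -> tuple[float, float]:
        return (float(self.pixels[:, 0].mean()), float(self.pixels[:, 1].mean()))


@dataclass(eq=False)
class PatchSet:
    """Size-filtered 8-connected components of the binarized ipsilateral label."""

    shape: tuple[int, int]
    patches: list[Patch] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patches)

    def __bool__(self) -> bool:
        return bool(self.patches)

    @property
    def union_mask(self) -> np.ndarray:
        """Binary mask of all retained patch pixels."""
        mask = np.zeros(self.shape, dtype=bool)
        for p in self.patches:
            mask[p.pixels[:, 0], p.pixels[:, 1]] = True
        return mask

    @property
    def total_pixels(self) -> int:
        return sum(p.size for p in self.patches)


def extract_patches(binary_mask: np.ndarray, min_size: int = MIN_PATCH_PIXELS) -> PatchSet:
    """Label 8-connected foreground components and retain those strictly
    larger than ``min_size`` pixels. An empty result is allowed."""
    binary_mask = np.asarray(binary_mask, dtype=bool)
    labels, n = ndimage.label(binary_mask, structure=_EIGHT)
    patches: list[Patch] = []
    if n:
        sizes = np.bincount(labels.ravel())
        for lab in range(1, n + 1):
            if sizes[lab] > min_size:
                patches.append(Patch(pixels=np.argwhere(labels == lab)))
    return PatchSet(shape=binary_mask.shape, patches=patches)
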