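"""Contralateral projection quantification: gap extraction and intensity
profiles.

The contralateral dLGN is almost fully labeled; the readout is the "gap",
the label-free central region normally occupied by the other eye's axons.
Pixels below a threshold ``beta * Mc`` (``Mc`` = mean of 10,000 pixels in
the ventrolateral monocular segment) split into the gap proper and
sub-threshold regions connected to the dLGN contour; the latter are removed
by flood-fill from the contour. Sections whose central hole itself reaches
the contour are flagged invalid and are meant to be discarded.

Profiles average a 40-pixel-wide strip running from the dorsomedial tip to
the ventrolateral end of the dLGN in 1-px bins; CTB profiles are normalized
by the mean of the final 200 bins (the monocular segment), marker profiles
by the whole-strip mean after no-primary-antibody background subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import (
    MonocularRegionError,
    StripError,
    ThresholdError,
)
from .section import SectionImage, dlgn_area, mask_boundary

#: Number of monocular-segment pixels averaged for the contralateral reference.
MONOCULAR_PIXELS = 10_000

#: Default proportionality coefficient of the contralateral threshold.
DEFAULT_BETA = 0.5

#: Transverse width of the profile strip, in pixels.
DEFAULT_STRIP_WIDTH = 40

#: Number of final strip bins forming the monocular normalization segment.
MONOCULAR_BINS = 200

#: Contour-connected sub-threshold components deeper than this (px from the
#: contour) indicate a gap that touches the contour -> section invalid.
DEFAULT_RIM_DEPTH = 5.0

_FOUR = ndimage.generate_binary_structure(2, 1)


def monocular_mean(section: SectionImage, n_pixels: int = MONOCULAR_PIXELS) -> float:
    """Mean intensity of the first ``n_pixels`` monocular-segment pixels in
    raster order (a deterministic subsample)."""
    if section.monocular_mask is None:
        raise MonocularRegionError("section has no monocular-segment annotation")
    idx = np.flatnonzero(section.monocular_mask.ravel())
    if idx.size < n_pixels:
        raise MonocularRegionError(
            f"monocular segment has {idx.size} px; {n_pixels} are required"
        )
    return float(section.intensity.ravel()[idx[:n_pixels]].mean())


def contra_threshold(mono_mean: float, beta: float = DEFAULT_BETA) -> float:
    """Contralateral threshold: ``beta`` times the monocular-segment mean."""
    if mono_mean <= 0:
        raise ThresholdError("monocular mean must be positive to set a threshold")
    if not 0 < beta < 1:
        raise ThresholdError("beta must lie strictly between 0 and 1")
    return float(beta * mono_mean)


@dataclass(frozen=True)
class GapResult:
    """Gap area and fraction; ``valid`` is False when the gap reached the
    dLGN contour and the section should be discarded."""

    area_um2: float | None
    fraction_pct: float | None
    valid: bool


def subthreshold_partition(
    section: SectionImage, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Partition sub-threshold dLGN pixels into (gap, contour-connected).

    Sub-threshold means strictly below ``threshold``. Components are
    4-connected (complementing the 8-connected foreground); a component is
    contour-connected when it contains a pixel of the mask boundary.
    """
    if threshold <= 0:
        raise ThresholdError("threshold must be positive")
    sub = section.dlgn_mask & (section.intensity < threshold)
    labels, n = ndimage.label(sub, structure=_FOUR)
    if n == 0:
        empty = np.zeros_like(sub)
        return empty, empty.copy()
    contour = mask_boundary(section.dlgn_mask)
    touching = np.unique(labels[contour & sub])
    touching = touching[touching > 0]
    excluded = np.isin(labels, touching) & sub
    gap = sub & ~excluded
    return gap, excluded


def gap_size(
    section: SectionImage, threshold: float, rim_depth: float = DEFAULT_RIM_DEPTH
) -> GapResult:
    """Measure the gap after flood-fill exclusion of contour-connected
    sub-threshold regions.

    When any excluded component penetrates deeper than ``rim_depth`` pixels
    from the contour, the central hole is taken to have merged with the
    contour and the section is flagged invalid (fraction unset).
    """
    gap, excluded = subthreshold_partition(section, threshold)
    if excluded.any():
        depth = ndimage.distance_transform_edt(section.dlgn_mask)
        if float(depth[excluded].max()) > rim_depth:
            return GapResult(area_um2=None, fraction_pct=None, valid=False)
    area = float(gap.sum()) * section.pixel_area_um2
    fraction = 100.0 * area / dlgn_area(section)
    return GapResult(area_um2=area, fraction_pct=fraction, valid=True)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class ProfileCurve:
    """Binned intensity profile along the dorsomedial->ventrolateral strip."""

    distance_um: np.ndarray
    values: np.ndarray
    raw: np.ndarray  # un-normalized per-bin means


def _strip_raw_means(section: SectionImage, width: int) -> np.ndarray:
    """Per-bin raw means of the strip from the dorsomedial tip through the
    ventrolateral tip to the last dLGN pixel along that direction.

    Bins are 1 px steps along the straight line; each bin averages ``width``
    transverse samples (bilinear interpolation). The strip must fit within
    the image.
    """
    d = np.asarray(section.landmarks.dm_tip, dtype=float)
    v = np.asarray(section.landmarks.vl_tip, dtype=float)
    u = v - d
    norm = np.hypot(*u)
    if norm == 0:
        raise StripError("dorsomedial and ventrolateral tips coincide")
    u = u / norm
    nvec = np.array([-u[1], u[0]])

    H, W = section.shape
    t = np.arange(int(np.ceil(np.hypot(H, W))) + 1, dtype=float)
    centers = d[None, :] + t[:, None] * u[None, :]
    rr = np.rint(centers[:, 0]).astype(int)
    cc = np.rint(centers[:, 1]).astype(int)
    inb = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
    inside = np.zeros(len(t), dtype=bool)
    inside[inb] = section.dlgn_mask[rr[inb], cc[inb]]
    if not inside.any():
        raise StripError("the strip does not intersect the dLGN mask")
    t_end = int(np.flatnonzero(inside).max())
    t = t[: t_end + 1]

    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    rows = d[0] + t[:, None] * u[0] + offsets[None, :] * nvec[0]
    cols = d[1] + t[:, None] * u[1] + offsets[None, :] * nvec[1]
    if rows.min() < 0 or rows.max() > H - 1 or cols.min() < 0 or cols.max() > W - 1:
        raise StripError("the profile strip does not fit inside the image")
    samples = ndimage.map_coordinates(
        section.intensity, np.stack([rows.ravel(), cols.ravel()]), order=1
    ).reshape(rows.shape)
    return samples.mean(axis=1)


def intensity_profile(
    section: SectionImage,
    width: int = DEFAULT_STRIP_WIDTH,
    mono_bins: int = MONOCULAR_BINS,
) -> ProfileCurve:
    """CTB intensity profile normalized by the monocular segment.

    Each 1x``width`` bin mean is divided by the mean of the final
    ``mono_bins`` bins' raw means (the ventrolateral monocular segment of
    the strip). The strip must be at least ``mono_bins`` bins long.
    """
    raw = _strip_raw_means(section, width)
    if len(raw) < mono_bins:
        raise StripError(
            f"strip has {len(raw)} bins; at least {mono_bins} are needed for normalization"
        )
    divisor = float(raw[-mono_bins:].mean())
    if divisor <= 0:
        raise StripError("monocular-segment normalization divisor is not positive")
    distance = np.arange(len(raw), dtype=float) * section.pixel_size_um
    return ProfileCurve(distance_um=distance, values=raw / divisor, raw=raw)


def normalize_marker_profile(raw: np.ndarray, no_primary_mean: float) -> np.ndarray:
    """Subtract the no-primary-antibody background (clamped at zero) and
    divide by the whole-strip average of the subtracted values."""
    if no_primary_mean < 0:
        raise ThresholdError("no-primary background must be non-negative")
    sub = np.maximum(np.asarray(raw, dtype=float) - no_primary_mean, 0.0)
    denom = float(sub.mean())
    if denom == 0:
        raise StripError("whole-strip average is zero after background subtraction")
    return sub / denom


def vglut1_profile(
    section: SectionImage,
    no_primary_mean: float,
    width: int = DEFAULT_STRIP_WIDTH,
) -> ProfileCurve:
    """VGLUT1-style profile: per-bin mean minus the no-primary-antibody
    control mean (clamped at 0), normalized by the whole-strip average."""
    raw = _strip_raw_means(section, width)
    values = normalize_marker_profile(raw, no_primary_mean)
    distance = np.arange(len(raw), dtype=float) * section.pixel_size_um
    return ProfileCurve(distance_um=distance, values=values, raw=raw)
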