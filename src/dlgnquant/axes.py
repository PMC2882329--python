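"""Patch extent along the anatomical axes of the dLGN.

Two chord constructions, both operating on the size-filtered ipsilateral
patches:

* dorsomedial-ventrolateral (DM-VL): sweep lines parallel to the chord
  connecting the dorsomedial and ventrolateral tips at 1-px offsets; on each
  line the patch extent is the distance between the outermost patch
  intersections; the line maximizing that extent also yields the dLGN chord,
  and the normalized extent is 100 * patch_span / nucleus_chord.
* outer-inner (O-I): a line through the patch centre of mass, perpendicular
  to the local tangent of the outer (optic-tract-adjacent) boundary; patch
  and dLGN spans along it give the normalized O-I extent.

Spans are pixel-quantized: sampling steps 1 px along the line and a span of
k consecutive hits measures k pixels (outermost minus innermost plus one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateTangentError, EmptyPatchSetError
from .ipsi import PatchSet
from .section import SectionImage

#: Number of outer-arc points used to fit the local boundary tangent.
DEFAULT_TANGENT_WINDOW = 11


@dataclass(frozen=True)
class AxisMeasurement:
    """Patch and nucleus extents (um) along one axis and their ratio (%)."""

    patch_span_um: float
    nucleus_span_um: float
    normalized_pct: float


def _line_spans(
    mask_list: list[np.ndarray],
    base: np.ndarray,
    u: np.ndarray,
    nvec: np.ndarray,
    offsets: np.ndarray,
    ts: np.ndarray,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """For every offset line ``base + o*nvec + t*u`` return (span, any_hit)
    per mask, with nearest-pixel sampling at 1-px steps along the line."""
    H, W = mask_list[0].shape
    rows = base[0] + offsets[:, None] * nvec[0] + ts[None, :] * u[0]
    cols = base[1] + offsets[:, None] * nvec[1] + ts[None, :] * u[1]
    rr = np.rint(rows).astype(int)
    cc = np.rint(cols).astype(int)
    valid = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
    rrc = np.clip(rr, 0, H - 1)
    ccc = np.clip(cc, 0, W - 1)
    out = []
    T = len(ts)
    for mask in mask_list:
        hits = np.zeros(rr.shape, dtype=bool)
        hits[valid] = mask[rrc[valid], ccc[valid]]
        any_hit = hits.any(axis=1)
        first = np.argmax(hits, axis=1)
        last = T - 1 - np.argmax(hits[:, ::-1], axis=1)
        span = np.where(any_hit, (ts[last] - ts[first]) + 1.0, 0.0)
        out.append((span, any_hit))
    return out


def _sweep_ranges(mask: np.ndarray, base: np.ndarray, u: np.ndarray, nvec: np.ndarray):
    pts = np.argwhere(mask).astype(float)
    rel = pts - base[None, :]
    o_proj = rel @ nvec
    t_proj = rel @ u
    offsets = np.arange(np.floor(o_proj.min()) - 1, np.ceil(o_proj.max()) + 2)
    ts = np.arange(np.floor(t_proj.min()) - 1, np.ceil(t_proj.max()) + 2)
    return offsets, ts


def dmvl_extent(section: SectionImage, patches: PatchSet) -> AxisMeasurement:
    """DM-VL extent: offset sweep of lines parallel to the tip-to-tip chord.

    The chosen line maximizes the patch span; ties are broken toward the
    larger dLGN chord, then toward the smaller absolute offset.
    """
    if not patches:
        raise EmptyPatchSetError("DM-VL length is undefined without patches")
    d = np.asarray(section.landmarks.dm_tip, dtype=float)
    v = np.asarray(section.landmarks.vl_tip, dtype=float)
    u = v - d
    norm = np.hypot(*u)
    if norm == 0:
        raise DegenerateTangentError("dorsomedial and ventrolateral tips coincide")
    u = u / norm
    nvec = np.array([-u[1], u[0]])
    offsets, ts = _sweep_ranges(section.dlgn_mask, d, u, nvec)
    (patch_span, _), (nuc_span, _) = _line_spans(
        [patches.union_mask, section.dlgn_mask], d, u, nvec, offsets, ts
    )
    # maximize patch span; tie-break: larger nucleus chord, then smaller |offset|
    order = np.lexsort((-np.abs(offsets), nuc_span, patch_span))
    best = order[-1]
    px = section.pixel_size_um
    q = float(patch_span[best])
    dv = float(nuc_span[best])
    return AxisMeasurement(
        patch_span_um=q * px,
        nucleus_span_um=dv * px,
        normalized_pct=100.0 * q / dv if dv else 0.0,
    )


def patch_centroid(patches: PatchSet) -> tuple[float, float]:
    """Unweighted centre of mass of the union of retained patch pixels."""
    if not patches:
        raise EmptyPatchSetError("centroid is undefined without patches")
    pts = np.concatenate([p.pixels for p in patches.patches])
    return (float(pts[:, 0].mean()), float(pts[:, 1].mean()))


def _outer_tangent(
    section: SectionImage, point: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Local tangent of the outer boundary near ``point``: least-squares
    (principal) direction of the ``window`` arc points closest along the arc
    to the point's nearest arc vertex. Returns (tangent_unit, nearest_vertex)."""
    arc = section.landmarks.outer_arc.astype(float)
    dists = np.hypot(arc[:, 0] - point[0], arc[:, 1] - point[1])
    i = int(np.argmin(dists))
    half = window // 2
    lo = max(0, i - half)
    hi = min(len(arc), lo + window)
    lo = max(0, hi - window)
    seg = arc[lo:hi]
    if len(seg) < 2 or np.allclose(seg, seg[0]):
        raise DegenerateTangentError("outer-arc window has no spatial extent")
    centered = seg - seg.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    tangent = vt[0] / np.hypot(*vt[0])
    radius = arc[i] - point
    rnorm = np.hypot(*radius)
    if rnorm > 0 and abs(float(tangent @ (radius / rnorm))) > 0.98:
        raise DegenerateTangentError("boundary tangent is collinear with the radius")
    return tangent, arc[i]


def oi_extent(
    section: SectionImage,
    patches: PatchSet,
    tangent_window: int = DEFAULT_TANGENT_WINDOW,
) -> AxisMeasurement:
    """O-I extent: chord perpendicular to the outer boundary through the
    patch centre of mass.

    A patch that the chord misses yields a zero patch span (reported, not an
    error); the dLGN span runs between the outermost boundary crossings
    along the chord.
    """
    if not patches:
        raise EmptyPatchSetError("O-I length is undefined without patches")
    c = np.asarray(patch_centroid(patches), dtype=float)
    tangent, _ = _outer_tangent(section, c, tangent_window)
    w = np.array([-tangent[1], tangent[0]])
    _, ts = _sweep_ranges(section.dlgn_mask, c, w, tangent)
    (patch_span, _), (nuc_span, _) = _line_spans(
        [patches.union_mask, section.dlgn_mask], c, w, tangent, np.array([0.0]), ts
    )
    px = section.pixel_size_um
    p = float(patch_span[0])
    lm = float(nuc_span[0])
    return AxisMeasurement(
        patch_span_um=p * px,
        nucleus_span_um=lm * px,
        normalized_pct=100.0 * p / lm if lm else 0.0,
    )
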