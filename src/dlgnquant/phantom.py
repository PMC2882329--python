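"""Synthetic dLGN section phantoms with known ground truth.

The nucleus is modeled as an annular (crescent) sector: two circular arcs
sharing a centre, the outer arc standing in for the optic-tract-adjacent
surface. The ipsilateral patch is an angular sub-sector intensity plateau
with controllable area fraction and axis extents; the contralateral
configuration labels the whole nucleus except a circular central gap.
Additive Gaussian noise and a smooth multiplicative illumination bias sit on
top. Every rendered section carries a truth record whose area fractions are
exact mask pixel counts and whose axis lengths are the chord constructions
evaluated on the noiseless true masks (with closed-form geometric targets
recorded alongside).

Cohort simulation has two distinct, labeled modes: drawing the *measured
endpoint* directly from printed (mean, SD, n) summaries for statistics
tests, and drawing per-animal *image parameters* for pipeline-recovery
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from . import axes, ipsi
from .exceptions import PhantomError
from .section import (
    Landmarks,
    SectionImage,
    SectionSeries,
    default_background_region,
    mask_boundary,
)
from .stats import GroupSummary


@dataclass(frozen=True)
class CrescentShape:
    """Annular-sector nucleus geometry (lengths in px = um at 1 um^2/px)."""

    outer_radius: float = 240.0
    inner_radius: float = 80.0
    angular_span: float = 1.8  # total span, radians

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise PhantomError("need 0 < inner_radius < outer_radius")
        if not 0 < self.angular_span < math.pi:
            raise PhantomError("angular span must lie in (0, pi)")

    @property
    def half_angle(self) -> float:
        return self.angular_span / 2.0

    @property
    def area(self) -> float:
        """Analytic nucleus area."""
        return self.half_angle * (self.outer_radius**2 - self.inner_radius**2)


@dataclass(frozen=True)
class PhantomSpec:
    """Full specification of one synthetic animal (section stack).

    ``kind`` selects the rendered configuration: ``"ipsi"`` (dark nucleus
    with an ipsilateral patch, controlled by ``patch_fraction`` or
    ``patch_axis_extents``) or ``"contra"`` (near-fully labeled nucleus with
    a central gap, controlled by ``gap_fraction``). ``valid_gap=False``
    deliberately opens the gap onto the nucleus contour to exercise the
    discard rule.
    """

    shape: CrescentShape = field(default_factory=CrescentShape)
    kind: str = "ipsi"
    patch_fraction: float = 0.15
    patch_axis_extents: tuple[float, float] | None = None  # (DM-VL %, O-I %)
    patch_radial_fraction: float = 0.5
    gap_fraction: float = 0.15
    valid_gap: bool = True
    label_intensity: float = 1100.0
    background_level: float = 100.0
    noise_sd: float = 0.0
    bias_amplitude: float = 0.0
    n_sections: int = 5
    orientation_deg: float = 0.0
    pixel_area_um2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ipsi", "contra"):
            raise PhantomError("kind must be 'ipsi' or 'contra'")
        if not 0 <= self.patch_fraction <= 0.9:
            raise PhantomError("patch_fraction must lie in [0, 0.9]")
        if not 0 <= self.gap_fraction <= 0.5:
            raise PhantomError("gap_fraction must lie in [0, 0.5]")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be non-negative")
        if self.background_level < 0 or self.label_intensity <= self.background_level:
            raise PhantomError("need 0 <= background_level < label_intensity")
        if self.n_sections < 5:
            raise PhantomError("need at least 5 sections (the five-section maximum)")
        if self.n_sections % 2 == 0:
            raise PhantomError("n_sections must be odd so the middle section is unique")
        if not 0 < self.patch_radial_fraction <= 1:
            raise PhantomError("patch_radial_fraction must lie in (0, 1]")

    @property
    def plateau(self) -> float:
        """Foreground signal above background (the post-subtraction plateau)."""
        return self.label_intensity - self.background_level


@dataclass
class SectionTruth:
    """Ground truth attached to one rendered section.

    Fractions are exact mask pixel-count ratios; axis lengths are the chord
    constructions on the noiseless true masks; ``target_*`` are the
    closed-form values the geometry was solved for.
    """

    section_index: int
    scale: float
    dlgn_area_px: int
    patch_area_px: int | None = None
    patch_fraction_pct: float | None = None
    gap_area_px: int | None = None
    gap_fraction_pct: float | None = None
    patch_span_dmvl_px: float | None = None
    nucleus_chord_dmvl_px: float | None = None
    normalized_dmvl_pct: float | None = None
    patch_span_oi_px: float | None = None
    nucleus_chord_oi_px: float | None = None
    normalized_oi_pct: float | None = None
    target_patch_fraction_pct: float | None = None
    target_gap_fraction_pct: float | None = None
    target_dmvl_pct: float | None = None
    target_oi_pct: float | None = None
    plateau: float = 0.0


# ---------------------------------------------------------------------------
# Geometry solving
# ---------------------------------------------------------------------------

def _patch_radii(shape: CrescentShape, radial_fraction: float) -> tuple[float, float]:
    mid = 0.5 * (shape.inner_radius + shape.outer_radius)
    half = 0.5 * radial_fraction * (shape.outer_radius - shape.inner_radius)
    return mid - half, mid + half


def _analytic_dmvl_pct(shape: CrescentShape, psi: float, b: float) -> float:
    """Closed-form normalized DM-VL extent of a centred angular-sector patch.

    The widest patch chord parallel to the tip-to-tip line passes through the
    patch's outer corners, at height h = b*cos(psi) above the arc centre;
    the nucleus chord there is bounded by the sector rays and the outer arc.
    """
    phi = shape.half_angle
    span_p = 2.0 * b * math.sin(psi)
    h = b * math.cos(psi)
    dv = 2.0 * min(h * math.tan(phi), math.sqrt(max(shape.outer_radius**2 - h**2, 0.0)))
    return 100.0 * span_p / dv if dv else 0.0


def _solve_patch_geometry(spec: PhantomSpec) -> tuple[float, float, float]:
    """Resolve (psi, a, b): patch angular half-width and radial band.

    With only ``patch_fraction`` given, the centred radial band makes the
    area relation exact: fraction = psi * radial_fraction / half_angle.
    With ``patch_axis_extents`` the O-I target fixes the band and the DM-VL
    target is solved by root finding on the closed-form chord ratio.
    """
    phi = spec.shape.half_angle
    if spec.patch_axis_extents is not None:
        e_dmvl, e_oi = spec.patch_axis_extents
        if not (0 < e_dmvl <= 100 and 0 < e_oi <= 100):
            raise PhantomError("patch_axis_extents must lie in (0, 100] percent")
        a, b = _patch_radii(spec.shape, e_oi / 100.0)
        top = _analytic_dmvl_pct(spec.shape, phi - 1e-9, b)
        if e_dmvl > top:
            raise PhantomError(
                f"DM-VL extent {e_dmvl}% unreachable (max {top:.1f}% for this geometry)"
            )
        psi = brentq(
            lambda p: _analytic_dmvl_pct(spec.shape, p, b) - e_dmvl, 1e-9, phi - 1e-9
        )
        return float(psi), a, b
    if spec.patch_fraction == 0:
        a, b = _patch_radii(spec.shape, spec.patch_radial_fraction)
        return 0.0, a, b
    psi = phi * spec.patch_fraction / spec.patch_radial_fraction
    if psi > phi:
        raise PhantomError(
            "patch_fraction too large for patch_radial_fraction; widen the radial band"
        )
    a, b = _patch_radii(spec.shape, spec.patch_radial_fraction)
    return float(psi), a, b


def _section_scale(index: int, n_sections: int) -> float:
    """Linear scale of section ``index``; unique maximum at the middle."""
    mid = n_sections // 2
    return 1.0 - 0.12 * abs(index - mid) / mid


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _canvas_and_center(shape: CrescentShape) -> tuple[int, int, float, float]:
    R = shape.outer_radius
    H = int(2 * R + 240)
    W = int(2 * R + 260)
    return H, W, 20.0 + R, 240.0 + R


def _primed_coords(H: int, W: int, cr: float, cc: float, theta: float):
    rows = np.arange(H, dtype=float)[:, None]
    cols = np.arange(W, dtype=float)[None, :]
    y = cr - rows
    x = cols - cc
    xp = x * math.cos(theta) + y * math.sin(theta)
    yp = -x * math.sin(theta) + y * math.cos(theta)
    return xp, yp


def _to_grid(xp: float, yp: float, cr: float, cc: float, theta: float) -> tuple[float, float]:
    x = xp * math.cos(theta) - yp * math.sin(theta)
    y = xp * math.sin(theta) + yp * math.cos(theta)
    return cr - y, cc + x


def _snap_to_boundary(points: np.ndarray, boundary: np.ndarray) -> np.ndarray:
    bpts = np.argwhere(boundary)
    tree = cKDTree(bpts)
    _, idx = tree.query(points)
    snapped = bpts[idx]
    keep = np.ones(len(snapped), dtype=bool)
    keep[1:] = np.any(snapped[1:] != snapped[:-1], axis=1)
    return snapped[keep]


def render_section(spec: PhantomSpec, section_index: int) -> tuple[SectionImage, SectionTruth]:
    """Render one section of the phantom stack with its truth record.

    Deterministic: identical (spec, section_index) yields bit-identical
    output. Only the noise realization depends on the seed; masks do not.
    """
    if not 0 <= section_index < spec.n_sections:
        raise PhantomError(f"section_index {section_index} outside [0, {spec.n_sections})")
    shape = spec.shape
    phi = shape.half_angle
    s = _section_scale(section_index, spec.n_sections)
    Ro, Ri = s * shape.outer_radius, s * shape.inner_radius
    psi, a0, b0 = _solve_patch_geometry(spec)
    a, b = s * a0, s * b0
    theta = math.radians(spec.orientation_deg)

    H, W, cr, cc = _canvas_and_center(shape)
    xp, yp = _primed_coords(H, W, cr, cc, theta)
    rad = np.hypot(xp, yp)
    ang = np.arctan2(xp, yp)  # angle from the outward (apex) direction

    dlgn = (rad >= Ri) & (rad <= Ro) & (np.abs(ang) <= phi)
    truth = SectionTruth(
        section_index=section_index,
        scale=s,
        dlgn_area_px=int(dlgn.sum()),
        plateau=spec.plateau,
    )

    patch = np.zeros_like(dlgn)
    gap = np.zeros_like(dlgn)
    if spec.kind == "ipsi":
        if psi > 0:
            patch = (rad >= a) & (rad <= b) & (np.abs(ang) <= psi) & dlgn
        foreground = patch
        truth.patch_area_px = int(patch.sum())
        truth.patch_fraction_pct = 100.0 * truth.patch_area_px / truth.dlgn_area_px
        truth.target_patch_fraction_pct = 100.0 * (psi / phi) * (b0**2 - a0**2) / (
            shape.outer_radius**2 - shape.inner_radius**2
        )
        truth.target_dmvl_pct = _analytic_dmvl_pct(shape, psi, b0) if psi > 0 else 0.0
        truth.target_oi_pct = (
            100.0 * (b0 - a0) / (shape.outer_radius - shape.inner_radius) if psi > 0 else 0.0
        )
    else:
        r_gap = 0.5 * (Ri + Ro)
        rho = s * math.sqrt(spec.gap_fraction * shape.area / math.pi)
        if spec.gap_fraction > 0:
            if spec.valid_gap:
                clearance = min(r_gap - Ri, Ro - r_gap, r_gap * math.sin(phi))
                if rho + 1.5 > clearance:
                    raise PhantomError(
                        "gap would touch the nucleus contour; reduce gap_fraction"
                    )
            else:
                r_gap = Ro  # deliberately open the gap onto the outer contour
            gap = ((xp - 0.0) ** 2 + (yp - r_gap) ** 2 <= rho**2) & dlgn
        foreground = dlgn & ~gap
        truth.gap_area_px = int(gap.sum())
        truth.gap_fraction_pct = 100.0 * truth.gap_area_px / truth.dlgn_area_px
        truth.target_gap_fraction_pct = 100.0 * spec.gap_fraction

    img = spec.background_level + spec.plateau * foreground.astype(float)
    if spec.bias_amplitude:
        u = 2.0 * np.arange(H)[:, None] / (H - 1) - 1.0
        v = 2.0 * np.arange(W)[None, :] / (W - 1) - 1.0
        img = img * (1.0 + spec.bias_amplitude * 0.5 * (u + v))
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, section_index])
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.rint(np.clip(img, 0.0, 65535.0))

    # landmarks: tips at the outer-arc corners, arc sampled at ~1 px steps
    boundary = mask_boundary(dlgn)
    n_arc = max(int(round(2 * phi * Ro)), 8)
    arc_angles = np.linspace(-phi, phi, n_arc)
    arc_pts = np.array(
        [
            _to_grid((Ro - 0.5) * math.sin(t), (Ro - 0.5) * math.cos(t), cr, cc, theta)
            for t in arc_angles
        ]
    )
    arc = _snap_to_boundary(arc_pts, boundary)
    dm = _snap_to_boundary(
        np.array([_to_grid(-Ro * math.sin(phi), Ro * math.cos(phi), cr, cc, theta)]), boundary
    )[0]
    vl = _snap_to_boundary(
        np.array([_to_grid(Ro * math.sin(phi), Ro * math.cos(phi), cr, cc, theta)]), boundary
    )[0]

    # ventrolateral monocular segment: angular band at the VL end, >= 10,500 px
    delta = min(2.0 * 10_500.0 / (Ro**2 - Ri**2), phi)
    mono = dlgn & (ang >= phi - delta)

    section = SectionImage(
        intensity=img,
        dlgn_mask=dlgn,
        landmarks=Landmarks(dm_tip=tuple(dm), vl_tip=tuple(vl), outer_arc=arc),
        monocular_mask=mono,
        background_region=default_background_region(dlgn),
        pixel_area_um2=spec.pixel_area_um2,
    )

    if spec.kind == "ipsi" and truth.patch_area_px:
        patches = ipsi.extract_patches(patch)
        dm_meas = axes.dmvl_extent(section, patches)
        oi_meas = axes.oi_extent(section, patches)
        px = section.pixel_size_um
        truth.patch_span_dmvl_px = dm_meas.patch_span_um / px
        truth.nucleus_chord_dmvl_px = dm_meas.nucleus_span_um / px
        truth.normalized_dmvl_pct = dm_meas.normalized_pct
        truth.patch_span_oi_px = oi_meas.patch_span_um / px
        truth.nucleus_chord_oi_px = oi_meas.nucleus_span_um / px
        truth.normalized_oi_pct = oi_meas.normalized_pct
    return section, truth


def make_series(spec: PhantomSpec) -> tuple[SectionSeries, list[SectionTruth]]:
    """Render the full rostral->caudal stack (50 um spacing); the dLGN area
    peaks at the middle section."""
    rendered = [render_section(spec, i) for i in range(spec.n_sections)]
    series = SectionSeries(sections=[sec for sec, _ in rendered])
    return series, [t for _, t in rendered]


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """One simulated group: per-animal values ~ Normal(mean, sd), truncated at 0."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise PhantomError("sd must be non-negative")
        if self.n < 2:
            raise PhantomError("each group needs n >= 2")


def simulate_cohort(
    groups: Sequence[CohortSpec], seed: int = 0
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Draw per-animal endpoint values for each group (endpoint mode).

    Returns a tidy table (animal, group, value) and the truth record of the
    raw draws keyed by group label.
    """
    rows = []
    truth: dict[str, np.ndarray] = {}
    for gi, g in enumerate(groups):
        rng = np.random.default_rng([seed, gi])
        values = np.maximum(rng.normal(g.mean, g.sd, size=g.n), 0.0)
        truth[g.label] = values
        for ai, v in enumerate(values):
            rows.append({"animal": f"{g.label}-{ai}", "group": g.label, "value": float(v)})
    return pd.DataFrame(rows), truth


@dataclass(frozen=True)
class ReferencePair:
    """A published two-group comparison: summaries plus the test the source
    reports for it (used to validate the variance gate)."""

    a: GroupSummary
    b: GroupSummary
    reported_test: str  # "student" | "welch"
    reported_p_bound: float | None  # printed significance bound, None if n.s.
    reported_p: float | None = None  # printed exact p for null results
    units: str = "%"


#: Printed group summaries of the enucleation/deprivation/TTX experiments.
REFERENCE_COHORTS: dict[str, ReferencePair] = {
    "me_p10_vs_control_fraction": ReferencePair(
        GroupSummary("ME-P10", 22.1, 3.6, 5), GroupSummary("control", 10.8, 1.2, 3),
        "student", 0.01,
    ),
    "me_p10_vs_control_gap": ReferencePair(
        GroupSummary("ME-P10", 3.16, 1.11, 4), GroupSummary("control", 16.46, 6.24, 4),
        "welch", 0.05,
    ),
    "me_p22_vs_control_fraction": ReferencePair(
        GroupSummary("ME-P22", 15.5, 1.2, 4), GroupSummary("control", 12.5, 1.7, 4),
        "student", 0.05,
    ),
    "me_p34_vs_control_fraction": ReferencePair(
        GroupSummary("ME-P34", 13.6, 0.5, 4), GroupSummary("control", 13.3, 3.7, 4),
        "welch", None, reported_p=0.91,
    ),
    "md_vs_control_fraction": ReferencePair(
        GroupSummary("MD", 9.8, 1.5, 4), GroupSummary("control", 10.8, 1.2, 3),
        "student", None, reported_p=0.46,
    ),
    "ttx_vs_saline_fraction": ReferencePair(
        GroupSummary("TTX", 15.2, 3.3, 18), GroupSummary("saline", 11.7, 1.1, 8),
        "welch", 0.01,
    ),
    "ttx_vs_me_fraction": ReferencePair(
        GroupSummary("TTX", 15.2, 3.3, 18), GroupSummary("ME", 20.7, 2.3, 3),
        "student", 0.05,
    ),
    "me_p10_vs_control_ipsi_area": ReferencePair(
        GroupSummary("ME-P10", 43673, 5990, 5), GroupSummary("control", 27858, 3294, 3),
        "student", 0.05, units="um^2",
    ),
    "me_p10_vs_control_dlgn_area": ReferencePair(
        GroupSummary("ME-P10", 198680, 15054, 5), GroupSummary("control", 257559, 6849, 3),
        "student", 0.01, units="um^2",
    ),
}


def cohort_preset(name: str) -> tuple[list[CohortSpec], ReferencePair]:
    """Cohort specs for a named reference comparison."""
    if name not in REFERENCE_COHORTS:
        raise PhantomError(
            f"unknown preset {name!r}; available: {sorted(REFERENCE_COHORTS)}"
        )
    ref = REFERENCE_COHORTS[name]
    return (
        [
            CohortSpec(ref.a.label, ref.a.mean, ref.a.sd, ref.a.n),
            CohortSpec(ref.b.label, ref.b.mean, ref.b.sd, ref.b.n),
        ],
        ref,
    )


def image_cohort_specs(
    groups: Sequence[CohortSpec],
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[tuple[str, str, PhantomSpec, float]]:
    """Image-parameter cohort mode: draw each animal's true patch fraction
    from its group distribution and build a per-animal PhantomSpec.

    Returns (animal_id, group_label, spec, drawn_fraction_pct) tuples.
    """
    base = base_spec if base_spec is not None else PhantomSpec()
    out = []
    for gi, g in enumerate(groups):
        rng = np.random.default_rng([seed, 7919, gi])
        draws = np.clip(rng.normal(g.mean, g.sd, size=g.n), 2.0, 60.0)
        for ai, v in enumerate(draws):
            spec = replace(
                base,
                kind="ipsi",
                patch_fraction=float(v) / 100.0,
                patch_axis_extents=None,
                seed=int(np.random.default_rng([seed, 7919, gi, ai]).integers(2**31)),
            )
            out.append((f"{g.label}-{ai}", g.label, spec, float(v)))
    return out
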