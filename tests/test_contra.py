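"""Contralateral gap extraction and intensity profiles."""

import numpy as np
import pytest

from dlgnquant.contra import (
    contra_threshold,
    gap_size,
    intensity_profile,
    monocular_mean,
    normalize_marker_profile,
    subthreshold_partition,
    vglut1_profile,
)
from dlgnquant.exceptions import MonocularRegionError, StripError, ThresholdError
from dlgnquant.phantom import PhantomSpec, render_section
from dlgnquant.section import estimate_background, subtract_background

import oracles
from conftest import make_rect_section


# ---------------------------------------------------------------------------
# Monocular reference and threshold
# ---------------------------------------------------------------------------

def _mono_section(values: np.ndarray):
    sec = make_rect_section(nrows=120, ncols=120, pad=25, intensity=None)
    mono = np.zeros_like(sec.dlgn_mask)
    mono[25:125, 25:125] = True  # 10,000 px inside the mask
    sec2 = make_rect_section(nrows=120, ncols=120, pad=25, monocular=mono)
    sec2.intensity[25:125, 25:125] = values
    return sec2


def test_monocular_mean_of_constant_region():
    assert monocular_mean(_mono_section(np.full((100, 100), 12.0))) == 12.0


def test_monocular_mean_of_half_and_half_region():
    values = np.zeros((100, 100))
    values[50:, :] = 20.0
    assert monocular_mean(_mono_section(values)) == 10.0


def test_monocular_mean_requires_ten_thousand_pixels():
    sec = make_rect_section(nrows=50, ncols=50, pad=25)
    mono = np.zeros_like(sec.dlgn_mask)
    mono[25:40, 25:40] = True
    sec = make_rect_section(nrows=50, ncols=50, pad=25, monocular=mono)
    with pytest.raises(MonocularRegionError):
        monocular_mean(sec)


def test_contra_threshold_is_beta_times_the_mean():
    assert contra_threshold(20.0, beta=0.5) == 10.0
    with pytest.raises(ThresholdError):
        contra_threshold(0.0)


def test_noiseless_phantom_monocular_mean_is_the_plateau(contra_section, contra_spec):
    sec, _ = contra_section
    sub = subtract_background(sec, estimate_background(sec))
    assert monocular_mean(sub) == contra_spec.plateau


# ---------------------------------------------------------------------------
# Gap extraction
# ---------------------------------------------------------------------------

def test_fully_labeled_nucleus_has_zero_valid_gap():
    sec = make_rect_section(nrows=20, ncols=20, pad=5)
    sec.intensity[sec.dlgn_mask] = 10.0
    gap = gap_size(sec, threshold=5.0)
    assert gap.valid and gap.area_um2 == 0.0 and gap.fraction_pct == 0.0


def test_toy_gap_with_rim_notch():
    """10x10 nucleus, 2x2 interior hole plus a 1-px notch on the rim: the
    notch is contour-connected and excluded, the hole alone is the gap."""
    sec = make_rect_section(nrows=10, ncols=10, pad=5)
    sec.intensity[sec.dlgn_mask] = 1.0
    sec.intensity[9:11, 9:11] = 0.0  # interior 2x2 hole
    sec.intensity[5, 7] = 0.0  # notch on the top rim
    gap = gap_size(sec, threshold=0.5)
    assert gap.valid
    assert gap.area_um2 == 4.0
    g, excluded = subthreshold_partition(sec, 0.5)
    assert int(g.sum()) == 4 and int(excluded.sum()) == 1


def test_partition_matches_bfs_flood_oracle_on_random_grids():
    rng = np.random.default_rng(99)
    for _ in range(20):
        sec = make_rect_section(nrows=20, ncols=20, pad=5)
        sub_pattern = rng.random((20, 20)) < 0.4
        sec.intensity[sec.dlgn_mask] = 1.0
        region = np.zeros_like(sec.dlgn_mask)
        region[5:25, 5:25] = sub_pattern
        sec.intensity[region] = 0.0
        gap, excluded = subthreshold_partition(sec, 0.5)
        oracle_excluded = oracles.flood_exclude_from_contour(
            region & sec.dlgn_mask, sec.dlgn_mask
        )
        assert np.array_equal(excluded, oracle_excluded)
        assert np.array_equal(gap, (region & sec.dlgn_mask) & ~oracle_excluded)


def test_pixel_partition_is_exact(contra_section, contra_spec):
    sec, _ = contra_section
    sub = subtract_background(sec, estimate_background(sec))
    threshold = contra_threshold(monocular_mean(sub))
    gap, excluded = subthreshold_partition(sub, threshold)
    supra = sub.dlgn_mask & (sub.intensity >= threshold)
    assert int(gap.sum()) + int(excluded.sum()) + int(supra.sum()) == int(sub.dlgn_mask.sum())


def test_gap_is_monotone_in_the_threshold(contra_section, contra_spec):
    sec, _ = contra_section
    sub = subtract_background(sec, estimate_background(sec))
    plateau = contra_spec.plateau
    fractions = []
    for t in np.linspace(0.1 * plateau, 0.9 * plateau, 9):
        gap = gap_size(sub, t)
        assert gap.valid
        fractions.append(gap.fraction_pct)
    assert all(a <= b for a, b in zip(fractions, fractions[1:]))


def test_gap_reaching_the_contour_invalidates_the_section():
    spec = PhantomSpec(kind="contra", gap_fraction=0.15, valid_gap=False)
    sec, _ = render_section(spec, 2)
    sub = subtract_background(sec, estimate_background(sec))
    gap = gap_size(sub, contra_threshold(monocular_mean(sub)))
    assert not gap.valid
    assert gap.area_um2 is None and gap.fraction_pct is None


def test_noiseless_phantom_gap_is_exact(contra_section, contra_spec):
    sec, truth = contra_section
    sub = subtract_background(sec, estimate_background(sec))
    gap = gap_size(sub, contra_threshold(monocular_mean(sub)))
    assert gap.valid
    assert gap.area_um2 == truth.gap_area_px * sec.pixel_area_um2


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def _strip_section(col_fn):
    """Wide rectangle whose intensity depends only on the column; the tip
    chord runs along the bottom edge (columns = distance)."""
    sec = make_rect_section(nrows=60, ncols=300, pad=25)
    cols = np.arange(sec.intensity.shape[1], dtype=float)[None, :]
    sec.intensity[:] = col_fn(cols)
    return sec


def test_uniform_image_profiles_to_one():
    sec = _strip_section(lambda c: np.full_like(c, 7.0))
    prof = intensity_profile(sec)
    assert np.allclose(prof.values, 1.0)
    assert len(prof.values) == 300
    assert np.all(np.diff(prof.distance_um) == 1.0)


def test_linear_ramp_profile_brackets_one():
    sec = _strip_section(lambda c: 1.0 + c / 300.0)
    prof = intensity_profile(sec)
    assert prof.values[0] < 1.0 < prof.values[-1]


def test_profile_is_invariant_to_intensity_scaling():
    rng = np.random.default_rng(5)
    sec = _strip_section(lambda c: 10.0 + (c % 17))
    sec.intensity += rng.uniform(0, 1, size=sec.intensity.shape)
    base = intensity_profile(sec).values
    sec.intensity *= 4.2
    scaled = intensity_profile(sec).values
    assert np.allclose(base, scaled)


def test_short_strip_is_rejected():
    sec = make_rect_section(nrows=60, ncols=100, pad=25)
    sec.intensity[:] = 1.0
    with pytest.raises(StripError):
        intensity_profile(sec)


def test_phantom_gap_crosses_the_profile(contra_section, contra_spec):
    sec, _ = contra_section
    sub = subtract_background(sec, estimate_background(sec))
    prof = intensity_profile(sub)
    # monocular end ~1.0; the gap pulls bins toward the background/plateau ratio (=0)
    assert prof.values.min() < 0.35
    assert np.median(prof.values) > 0.9


def test_marker_profile_normalization_arithmetic():
    out = normalize_marker_profile(np.array([2.0, 2.0, 4.0, 4.0]), no_primary_mean=0.0)
    assert np.allclose(out, [2 / 3, 2 / 3, 4 / 3, 4 / 3])


def test_marker_profile_uniform_is_one_and_zero_divisor_errors():
    sec = _strip_section(lambda c: np.full_like(c, 3.0))
    prof = vglut1_profile(sec, no_primary_mean=0.0)
    assert np.allclose(prof.values, 1.0)
    with pytest.raises(StripError):
        vglut1_profile(sec, no_primary_mean=3.0)  # background equals the signal
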