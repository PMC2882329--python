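"""Section containers, I/O, analysis-section selection, background handling."""

import dataclasses

import numpy as np
import pytest

from dlgnquant.exceptions import (
    BackgroundPlacementError,
    EmptyMaskError,
    InsufficientSectionsError,
    MissingLandmarkError,
    ShapeMismatchError,
)
from dlgnquant.section import (
    SectionSeries,
    dlgn_area,
    estimate_background,
    read_section,
    read_series,
    select_analysis_section,
    subtract_background,
    write_section,
    write_series,
)

from conftest import make_rect_section


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_phantom_triplet_roundtrips_losslessly(tmp_path, ipsi_section):
    sec, _ = ipsi_section
    paths = (tmp_path / "img.tif", tmp_path / "mask.tif", tmp_path / "lm.json")
    write_section(sec, *paths, monocular_path=tmp_path / "mono.tif")
    back = read_section(*paths)
    assert np.array_equal(back.intensity, sec.intensity)
    assert np.array_equal(back.dlgn_mask, sec.dlgn_mask)
    assert np.array_equal(back.monocular_mask, sec.monocular_mask)
    assert back.landmarks.dm_tip == sec.landmarks.dm_tip
    assert back.landmarks.vl_tip == sec.landmarks.vl_tip
    assert np.array_equal(back.landmarks.outer_arc, sec.landmarks.outer_arc)
    assert back.background_region == tuple(sec.background_region)
    assert back.pixel_area_um2 == sec.pixel_area_um2


def test_series_roundtrip(tmp_path, ipsi_series):
    series, _ = ipsi_series
    manifest = write_series(series, tmp_path / "series")
    back = read_series(manifest)
    assert len(back) == len(series)
    assert back.spacing_um == 50.0
    assert np.array_equal(back[0].intensity, series[0].intensity)


def test_mask_shape_mismatch_is_rejected(tmp_path, ipsi_section):
    sec, _ = ipsi_section
    paths = (tmp_path / "img.tif", tmp_path / "mask.tif", tmp_path / "lm.json")
    write_section(sec, *paths)
    import tifffile

    tifffile.imwrite(paths[1], np.zeros((10, 10), dtype=np.uint8))
    with pytest.raises(ShapeMismatchError):
        read_section(*paths)


def test_missing_landmark_key_is_rejected(tmp_path, ipsi_section):
    import json

    sec, _ = ipsi_section
    paths = (tmp_path / "img.tif", tmp_path / "mask.tif", tmp_path / "lm.json")
    write_section(sec, *paths)
    payload = json.loads(paths[2].read_text())
    del payload["dm_tip"]
    paths[2].write_text(json.dumps(payload))
    with pytest.raises(MissingLandmarkError):
        read_section(*paths)


def test_empty_mask_is_rejected():
    sec = make_rect_section(nrows=10, ncols=10, pad=5)
    with pytest.raises(EmptyMaskError):
        dataclasses.replace(sec, dlgn_mask=np.zeros_like(sec.dlgn_mask))


# ---------------------------------------------------------------------------
# Analysis-section selection
# ---------------------------------------------------------------------------

def _series_with_areas(side_lengths):
    sections = [make_rect_section(nrows=s, ncols=s, pad=5) for s in side_lengths]
    return SectionSeries(sections=sections)


def test_selects_two_sections_rostral_of_the_largest():
    # areas rostral->caudal 100, 400, 900, 625, 225 -> argmax at 2 -> index 0
    assert select_analysis_section(_series_with_areas([10, 20, 30, 25, 15])) == 0


def test_rejects_series_without_rostral_coverage():
    with pytest.raises(InsufficientSectionsError):
        select_analysis_section(_series_with_areas([30, 20, 10]))


def test_area_ties_break_toward_the_rostral_section():
    # tie at indices 1 and 2 -> rostral tie wins -> argmax 1 -> index -1 -> error
    with pytest.raises(InsufficientSectionsError):
        select_analysis_section(_series_with_areas([10, 30, 30, 20, 10]))


def test_selection_is_invariant_to_intensity_rescaling():
    series = _series_with_areas([10, 20, 30, 25, 15])
    idx = select_analysis_section(series)
    scaled = SectionSeries(
        sections=[
            dataclasses.replace(s, intensity=s.intensity * 5 + 3) for s in series.sections
        ]
    )
    assert select_analysis_section(scaled) == idx


# ---------------------------------------------------------------------------
# Background estimation and subtraction
# ---------------------------------------------------------------------------

def _bg_section(fill):
    """Small nucleus in the top-right of a 400x400 canvas; the 200x200
    background square sits well away from it (down-left)."""
    from dlgnquant.section import Landmarks, SectionImage

    intensity = np.full((400, 400), float(fill))
    mask = np.zeros((400, 400), dtype=bool)
    mask[10:30, 360:380] = True
    arc = np.array([[10, c] for c in range(360, 380)])
    return SectionImage(
        intensity=intensity,
        dlgn_mask=mask,
        landmarks=Landmarks(dm_tip=(29, 360), vl_tip=(29, 379), outer_arc=arc),
        background_region=(150, 50, 200, 200),
    )


def test_background_of_constant_region_is_that_constant():
    assert estimate_background(_bg_section(7.0)) == 7.0


def test_background_of_half_and_half_region_is_the_midpoint():
    sec = _bg_section(0.0)
    sec.intensity[150:250, 50:250] = 10.0  # top half of the 200x200 region
    assert estimate_background(sec) == 5.0


def test_background_region_must_hold_exactly_40000_pixels():
    sec = _bg_section(1.0)
    with pytest.raises(BackgroundPlacementError):
        estimate_background(sec, region=(0, 0, 100, 100))


def test_background_region_may_not_overlap_the_dlgn():
    sec = _bg_section(1.0)
    with pytest.raises(BackgroundPlacementError):
        estimate_background(sec, region=(0, 200, 200, 200))


def test_phantom_background_recovers_the_known_level(ipsi_section, ipsi_spec):
    sec, _ = ipsi_section
    assert estimate_background(sec) == ipsi_spec.background_level


def test_subtraction_clamps_and_is_monotone():
    sec = _bg_section(5.0)
    out = subtract_background(sec, 7.0)
    assert np.all(out.intensity == 0.0)
    assert np.all(out.intensity <= sec.intensity)
    assert np.array_equal(out.dlgn_mask, sec.dlgn_mask)


def test_subtraction_identity_and_idempotence_without_clamping():
    sec = _bg_section(10.0)
    assert np.array_equal(subtract_background(sec, 0.0).intensity, sec.intensity)
    once = subtract_background(sec, 3.0)
    # no pixel clamped -> subtracting 0 afterwards changes nothing
    again = subtract_background(once, 0.0)
    assert np.array_equal(once.intensity, again.intensity)


def test_dlgn_area_is_pixel_count_times_pixel_area(ipsi_section):
    sec10 = make_rect_section(nrows=10, ncols=10, pad=5)
    assert dlgn_area(sec10) == 100.0
    sec, truth = ipsi_section
    assert dlgn_area(sec) == truth.dlgn_area_px * sec.pixel_area_um2
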