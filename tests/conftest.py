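"""Shared fixtures: toy rectangular sections with exact hand-checkable
geometry, and session-cached phantom renders (rendering is the expensive
step, the measurements are cheap)."""

from __future__ import annotations

import numpy as np
import pytest

from dlgnquant.phantom import PhantomSpec, make_series, render_section
from dlgnquant.section import Landmarks, SectionImage


def make_rect_section(
    nrows: int = 100,
    ncols: int = 200,
    pad: int = 25,
    intensity: np.ndarray | None = None,
    monocular: np.ndarray | None = None,
    background_region: tuple | None = None,
) -> SectionImage:
    """Axis-aligned rectangular 'nucleus': mask rows pad..pad+nrows-1 and
    cols pad..pad+ncols-1; tips at the bottom corners (the tip chord is
    horizontal), outer boundary along the top edge."""
    H, W = nrows + 2 * pad, ncols + 2 * pad
    mask = np.zeros((H, W), dtype=bool)
    mask[pad : pad + nrows, pad : pad + ncols] = True
    if intensity is None:
        intensity = np.zeros((H, W))
    arc = np.array([[pad, c] for c in range(pad, pad + ncols)])
    return SectionImage(
        intensity=intensity,
        dlgn_mask=mask,
        landmarks=Landmarks(
            dm_tip=(pad + nrows - 1, pad),
            vl_tip=(pad + nrows - 1, pad + ncols - 1),
            outer_arc=arc,
        ),
        monocular_mask=monocular,
        background_region=background_region,
    )


@pytest.fixture(scope="session")
def ipsi_spec() -> PhantomSpec:
    return PhantomSpec(kind="ipsi", patch_fraction=0.20, seed=0)


@pytest.fixture(scope="session")
def ipsi_series(ipsi_spec):
    return make_series(ipsi_spec)


@pytest.fixture(scope="session")
def ipsi_section(ipsi_spec):
    return render_section(ipsi_spec, ipsi_spec.n_sections // 2)


@pytest.fixture(scope="session")
def contra_spec() -> PhantomSpec:
    return PhantomSpec(kind="contra", gap_fraction=0.15, seed=0)


@pytest.fixture(scope="session")
def contra_section(contra_spec):
    return render_section(contra_spec, contra_spec.n_sections // 2)


@pytest.fixture(scope="session")
def contra_series(contra_spec):
    return make_series(contra_spec)
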