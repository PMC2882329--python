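"""Section containers, file I/O, analysis-section selection and background
subtraction.

A :class:`SectionImage` bundles one coronal fluorescence section: the
intensity grid (arbitrary units), the dLGN boundary mask, anatomical
landmarks (dorsomedial tip, ventrolateral tip, the outer optic-tract-adjacent
boundary arc), the ventrolateral monocular-segment mask used as the
contralateral normalization reference, and the placement of the 40,000-pixel
background-reference region.

Coordinates are row-major, origin at the top-left, 0-based; pixels are unit
squares of ``pixel_area_um2`` (default 1.00 um^2/px). Within a
:class:`SectionSeries` the rostral end is index 0 and consecutive sections
are ``spacing_um`` (default 50 um) apart, so "100 um rostral" of a section
means two indices earlier.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage

from .exceptions import (
    BackgroundPlacementError,
    EmptyMaskError,
    InsufficientSectionsError,
    LandmarkError,
    MissingLandmarkError,
    ShapeMismatchError,
)

#: Number of pixels in the background-reference region ventromedial to the dLGN.
BACKGROUND_PIXELS = 40_000

#: Default rostro-caudal spacing between consecutive serial sections.
DEFAULT_SPACING_UM = 50.0


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a binary mask (4-connected inner boundary)."""
    mask = np.asarray(mask, dtype=bool)
    return mask & ~ndimage.binary_erosion(mask)


@dataclass(eq=False)
class Landmarks:
    """Anatomical landmarks of one section.

    ``dm_tip`` and ``vl_tip`` are the dorsomedial and ventrolateral tips of
    the dLGN where it touches the optic tract; ``outer_arc`` is the ordered
    chain of boundary pixels along the optic-tract-adjacent (outer) border,
    running from the dorsomedial to the ventrolateral tip.
    """

    dm_tip: tuple[int, int]
    vl_tip: tuple[int, int]
    outer_arc: np.ndarray  # (N, 2) int array of (row, col)

    def __post_init__(self) -> None:
        self.dm_tip = (int(self.dm_tip[0]), int(self.dm_tip[1]))
        self.vl_tip = (int(self.vl_tip[0]), int(self.vl_tip[1]))
        arc = np.asarray(self.outer_arc, dtype=int)
        if arc.ndim != 2 or arc.shape[1] != 2 or len(arc) < 2:
            raise LandmarkError("outer_arc must be an (N>=2, 2) array of pixel coordinates")
        self.outer_arc = arc


@dataclass(eq=False)
class SectionImage:
    """One coronal section with its mask, landmarks and annotations."""

    intensity: np.ndarray
    dlgn_mask: np.ndarray
    landmarks: Landmarks
    monocular_mask: np.ndarray | None = None
    background_region: tuple[int, int, int, int] | None = None  # (r0, c0, h, w)
    pixel_area_um2: float = 1.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.dlgn_mask = np.asarray(self.dlgn_mask, dtype=bool)
        if self.intensity.ndim != 2:
            raise ShapeMismatchError("intensity must be a 2-D grid")
        if self.intensity.shape != self.dlgn_mask.shape:
            raise ShapeMismatchError(
                f"mask shape {self.dlgn_mask.shape} != image shape {self.intensity.shape}"
            )
        if not self.dlgn_mask.any():
            raise EmptyMaskError("dLGN mask is empty")
        if np.any(self.intensity < 0):
            raise ShapeMismatchError("intensity values must be non-negative")
        if self.monocular_mask is not None:
            self.monocular_mask = np.asarray(self.monocular_mask, dtype=bool)
            if self.monocular_mask.shape != self.dlgn_mask.shape:
                raise ShapeMismatchError("monocular mask shape differs from image shape")
            if np.any(self.monocular_mask & ~self.dlgn_mask):
                raise LandmarkError("monocular region must lie inside the dLGN mask")
        if self.pixel_area_um2 <= 0:
            raise ShapeMismatchError("pixel_area_um2 must be positive")
        self._validate_landmarks()

    def _validate_landmarks(self) -> None:
        boundary = mask_boundary(self.dlgn_mask)
        for name, pt in (("dm_tip", self.landmarks.dm_tip), ("vl_tip", self.landmarks.vl_tip)):
            r, c = pt
            if not (0 <= r < boundary.shape[0] and 0 <= c < boundary.shape[1]) or not boundary[r, c]:
                raise LandmarkError(f"{name} {pt} does not lie on the dLGN mask boundary")
        arc = self.landmarks.outer_arc
        if (
            np.any(arc < 0)
            or np.any(arc[:, 0] >= boundary.shape[0])
            or np.any(arc[:, 1] >= boundary.shape[1])
            or not boundary[arc[:, 0], arc[:, 1]].all()
        ):
            raise LandmarkError("outer_arc coordinates must lie on the dLGN mask boundary")

    @property
    def pixel_size_um(self) -> float:
        """Linear pixel pitch in micrometres."""
        return float(np.sqrt(self.pixel_area_um2))

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass(eq=False)
class SectionSeries:
    """Rostral-to-caudal ordered serial sections at fixed spacing."""

    sections: list[SectionImage]
    spacing_um: float = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        if not self.sections:
            raise InsufficientSectionsError("a series needs at least one section")
        areas = {s.pixel_area_um2 for s in self.sections}
        if len(areas) != 1:
            raise ShapeMismatchError("all sections in a series must share pixel_area_um2")

    def __len__(self) -> int:
        return len(self.sections)

    def __getitem__(self, i: int) -> SectionImage:
        return self.sections[i]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def dlgn_area(section: SectionImage) -> float:
    """Size of the dLGN in um^2: mask pixel count times pixel area."""
    return float(section.dlgn_mask.sum()) * section.pixel_area_um2


def select_analysis_section(series: SectionSeries) -> int:
    """Index of the analysis section: 100 um rostral (two sections) of the
    section with the largest dLGN area.

    Ties in the area maximum are broken toward the more rostral (lower-index)
    section. Raises :class:`InsufficientSectionsError` when the argmax sits
    too close to the rostral end for a section 100 um rostral to exist.
    """
    if len(series) < 3:
        raise InsufficientSectionsError("need at least 3 sections to step 100 um rostral")
    areas = np.array([dlgn_area(s) for s in series.sections])
    argmax = int(np.argmax(areas))  # first occurrence == most rostral tie
    idx = argmax - 2
    if idx < 0:
        raise InsufficientSectionsError(
            f"largest dLGN area at index {argmax}; no section 100 um rostral exists"
        )
    return idx


def estimate_background(
    section: SectionImage, region: tuple[int, int, int, int] | None = None
) -> float:
    """Mean intensity of the 40,000-pixel background region ventromedial to
    the dLGN.

    ``region`` is (r0, c0, h, w); defaults to the section's stored placement.
    The region must contain exactly :data:`BACKGROUND_PIXELS` pixels, lie
    inside the image and be disjoint from the dLGN mask.
    """
    region = region if region is not None else section.background_region
    if region is None:
        raise BackgroundPlacementError("no background region stored on the section")
    r0, c0, h, w = (int(v) for v in region)
    if h <= 0 or w <= 0 or h * w != BACKGROUND_PIXELS:
        raise BackgroundPlacementError(
            f"background region must contain exactly {BACKGROUND_PIXELS} pixels, got {h}x{w}"
        )
    H, W = section.shape
    if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
        raise BackgroundPlacementError("background region exceeds the image bounds")
    if section.dlgn_mask[r0 : r0 + h, c0 : c0 + w].any():
        raise BackgroundPlacementError("background region overlaps the dLGN")
    return float(section.intensity[r0 : r0 + h, c0 : c0 + w].mean())


def default_background_region(
    mask: np.ndarray, side: int = 200, offset: int = 10
) -> tuple[int, int, int, int]:
    """Default placement: a ``side`` x ``side`` square whose top-right corner
    sits ``offset`` px down-left (ventromedial) of the dLGN bounding box."""
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    if rows.size == 0:
        raise EmptyMaskError("cannot place a background region for an empty mask")
    r0 = int(rows.max()) + offset
    c1 = int(cols.min()) - offset
    return (r0, c1 - side, side, side)


def subtract_background(section: SectionImage, background: float) -> SectionImage:
    """Subtract a scalar background, clamping at zero; mask and landmarks
    are carried over unchanged."""
    if background < 0:
        raise BackgroundPlacementError("background must be non-negative")
    return dataclasses.replace(
        section, intensity=np.maximum(section.intensity - float(background), 0.0)
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_LANDMARK_KEYS = ("dm_tip", "vl_tip", "outer_arc")


def write_section(
    section: SectionImage,
    image_path: str | Path,
    mask_path: str | Path,
    landmarks_path: str | Path,
    monocular_path: str | Path | None = None,
) -> None:
    """Write one section as 16-bit grayscale TIFF + 8-bit mask TIFF + JSON
    landmarks. Intensities must already be integral and fit in 16 bits."""
    img = np.asarray(section.intensity)
    if img.max(initial=0) > 65535:
        raise ShapeMismatchError("intensity exceeds the 16-bit range")
    tifffile.imwrite(image_path, np.round(img).astype(np.uint16))
    tifffile.imwrite(mask_path, (section.dlgn_mask.astype(np.uint8) * 255))
    payload: dict = {
        "dm_tip": list(section.landmarks.dm_tip),
        "vl_tip": list(section.landmarks.vl_tip),
        "outer_arc": section.landmarks.outer_arc.tolist(),
        "pixel_area_um2": section.pixel_area_um2,
        "background_region": (
            list(section.background_region) if section.background_region else None
        ),
        "monocular_region": None,
    }
    if section.monocular_mask is not None:
        if monocular_path is None:
            monocular_path = Path(landmarks_path).with_suffix(".mono.tif")
        tifffile.imwrite(monocular_path, section.monocular_mask.astype(np.uint8) * 255)
        payload["monocular_region"] = Path(monocular_path).name
    Path(landmarks_path).write_text(json.dumps(payload))


def read_section(
    image_path: str | Path, mask_path: str | Path, landmarks_path: str | Path
) -> SectionImage:
    """Read the (image, mask, landmarks) triplet written by
    :func:`write_section` into a fully populated :class:`SectionImage`."""
    img = np.asarray(tifffile.imread(image_path), dtype=float)
    mask = np.asarray(tifffile.imread(mask_path)) > 0
    if mask.shape != img.shape:
        raise ShapeMismatchError(f"mask shape {mask.shape} != image shape {img.shape}")
    payload = json.loads(Path(landmarks_path).read_text())
    for key in _LANDMARK_KEYS:
        if key not in payload:
            raise MissingLandmarkError(f"landmarks file lacks required key {key!r}")
    landmarks = Landmarks(
        dm_tip=tuple(payload["dm_tip"]),
        vl_tip=tuple(payload["vl_tip"]),
        outer_arc=np.asarray(payload["outer_arc"], dtype=int),
    )
    mono = None
    if payload.get("monocular_region"):
        mono_path = Path(landmarks_path).parent / payload["monocular_region"]
        mono = np.asarray(tifffile.imread(mono_path)) > 0
    bg = payload.get("background_region")
    return SectionImage(
        intensity=img,
        dlgn_mask=mask,
        landmarks=landmarks,
        monocular_mask=mono,
        background_region=tuple(bg) if bg else None,
        pixel_area_um2=float(payload.get("pixel_area_um2", 1.0)),
    )


def write_series(series: SectionSeries, directory: str | Path, prefix: str = "section") -> Path:
    """Write every section of a series plus a rostral->caudal manifest YAML.

    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, sec in enumerate(series.sections):
        names = {
            "image": f"{prefix}_{i:03d}.tif",
            "mask": f"{prefix}_{i:03d}_mask.tif",
            "landmarks": f"{prefix}_{i:03d}_landmarks.json",
        }
        write_section(
            sec,
            directory / names["image"],
            directory / names["mask"],
            directory / names["landmarks"],
            directory / f"{prefix}_{i:03d}_mono.tif",
        )
        entries.append(names)
    manifest = {
        "order": "rostral_to_caudal",
        "spacing_um": series.spacing_um,
        "sections": entries,
    }
    path = directory / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest))
    return path


def read_series(manifest_path: str | Path) -> SectionSeries:
    """Read a series manifest written by :func:`write_series`."""
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    sections = [
        read_section(base / e["image"], base / e["mask"], base / e["landmarks"])
        for e in manifest["sections"]
    ]
    return SectionSeries(sections=sections, spacing_um=float(manifest["spacing_um"]))
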