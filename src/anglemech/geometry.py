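"""Physical-coordinate model, label masks, I/O, validation and orientation.

Single-angle anterior-segment UBM images come in two acquisition geometries:
half-frame (9.75 mm x 6.00 mm scan range) and panorama (15.50 mm x 9.50 mm).
Both are stored as H x W integer label rasters with the fixed encoding

    0 = background, 1 = iris, 2 = sclera, 3 = ciliary body.

All downstream biometry is expressed in micrometres through a per-axis
:class:`PhysicalSpacing`, never through a single scalar pitch: the two modes
have unequal axis pitches, so every physical length goes through
:func:`physical_distance`.

Coordinate convention: 0-based (row, col), origin at the top-left corner,
subpixel coordinates allowed everywhere downstream.  A pixel (i, j) covers
the unit square centred on (i, j); physical position of a subpixel point is
(col * um_per_px_x, row * um_per_px_y).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage import measure

__all__ = [
    "BACKGROUND",
    "IRIS",
    "SCLERA",
    "CILIARY",
    "LABEL_NAMES",
    "SMALL_OBJECT_PX",
    "AcquisitionMode",
    "PhysicalSpacing",
    "PixelPoint",
    "SegmentationMask",
    "ValidationReport",
    "AngleMechError",
    "InvalidGeometryError",
    "PaletteError",
    "MissingClassError",
    "OrientationError",
    "spacing_for_mode",
    "physical_distance",
    "read_mask",
    "write_mask",
    "validate_mask",
    "normalize_orientation",
    "region_boundary",
]

# ---------------------------------------------------------------------------
# label encoding and tunables

BACKGROUND = 0
IRIS = 1
SCLERA = 2
CILIARY = 3
LABEL_NAMES = {BACKGROUND: "background", IRIS: "iris", SCLERA: "sclera", CILIARY: "ciliary body"}

#: connected components smaller than this are treated as segmentation speckle
SMALL_OBJECT_PX = 50

#: default PNG palette: file pixel value -> label value (identity)
DEFAULT_PALETTE: Mapping[int, int] = {0: 0, 1: 1, 2: 2, 3: 3}


class AngleMechError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(AngleMechError):
    pass


class PaletteError(AngleMechError):
    pass


class MissingClassError(AngleMechError):
    pass


class OrientationError(AngleMechError):
    pass


# ---------------------------------------------------------------------------
# acquisition geometry

class AcquisitionMode(str, Enum):
    """UBM acquisition geometry; fixes the physical scan range."""

    HALF_FRAME = "half_frame"
    PANORAMA = "panorama"

    @property
    def scan_range_mm(self) -> tuple[float, float]:
        """(width, height) of the scanned field in millimetres."""
        return _SCAN_RANGE_MM[self]


_SCAN_RANGE_MM = {
    AcquisitionMode.HALF_FRAME: (9.75, 6.00),
    AcquisitionMode.PANORAMA: (15.50, 9.50),
}


@dataclass(frozen=True)
class PhysicalSpacing:
    """Micrometres per pixel, per axis (anisotropic in general)."""

    um_per_px_x: float
    um_per_px_y: float

    def __post_init__(self) -> None:
        for v in (self.um_per_px_x, self.um_per_px_y):
            if not np.isfinite(v) or v <= 0:
                raise InvalidGeometryError(f"spacing must be finite and positive, got {v!r}")


@dataclass(frozen=True)
class PixelPoint:
    """Subpixel image point, 0-based (row, col), origin top-left."""

    row: float
    col: float

    def as_array(self) -> np.ndarray:
        return np.array([self.row, self.col], dtype=float)


def spacing_for_mode(mode: AcquisitionMode, width_px: int, height_px: int) -> PhysicalSpacing:
    """Pixel pitch implied by the mode's scan range over the actual raster.

    The scan range is fixed per acquisition mode; spacing is always derived
    from the actual raster dimensions so non-standard rasters degrade
    gracefully.
    """
    if width_px <= 0 or height_px <= 0:
        raise InvalidGeometryError(
            f"raster dimensions must be positive, got {width_px} x {height_px}"
        )
    w_mm, h_mm = mode.scan_range_mm
    return PhysicalSpacing(
        um_per_px_x=w_mm * 1000.0 / width_px,
        um_per_px_y=h_mm * 1000.0 / height_px,
    )


def physical_distance(a: PixelPoint, b: PixelPoint, spacing: PhysicalSpacing) -> float:
    """Euclidean distance in micrometres after per-axis scaling."""
    dx = (a.col - b.col) * spacing.um_per_px_x
    dy = (a.row - b.row) * spacing.um_per_px_y
    return float(np.hypot(dx, dy))


# ---------------------------------------------------------------------------
# mask container

@dataclass
class SegmentationMask:
    """Tissue-label raster with acquisition mode and physical spacing.

    ``flipped`` records whether :func:`normalize_orientation` mirrored the
    raster so the angle recess lies in the left half.
    """

    labels: np.ndarray
    mode: AcquisitionMode
    spacing: PhysicalSpacing = field(default=None)  # type: ignore[assignment]
    flipped: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise InvalidGeometryError("labels must be a 2-D raster")
        if self.spacing is None:
            h, w = self.labels.shape
            self.spacing = spacing_for_mode(self.mode, w, h)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def tissue(self, label: int) -> np.ndarray:
        """Boolean indicator raster of one tissue class."""
        return self.labels == label

    def to_physical(self, p: PixelPoint) -> tuple[float, float]:
        """(x_um, y_um) position of a subpixel point."""
        return (p.col * self.spacing.um_per_px_x, p.row * self.spacing.um_per_px_y)


# ---------------------------------------------------------------------------
# I/O: indexed/grayscale PNG label masks, bit-exact round trip

def write_mask(mask: SegmentationMask, path: str | Path, palette: Mapping[int, int] | None = None,
               sidecar: bool = True) -> None:
    """Write an indexed PNG (label -> pixel value per ``palette``).

    A JSON sidecar ``<path>.json`` records acquisition mode and flip flag so
    :func:`read_mask` can restore the full container.
    """
    path = Path(path)
    palette = dict(palette or DEFAULT_PALETTE)
    inv = {lab: px for px, lab in palette.items()}
    missing = set(np.unique(mask.labels).tolist()) - set(inv)
    if missing:
        raise PaletteError(f"labels {sorted(missing)} not covered by palette")
    raster = np.zeros_like(mask.labels, dtype=np.uint8)
    for lab, px in inv.items():
        raster[mask.labels == lab] = px
    img = Image.fromarray(raster, mode="L").convert("P")
    # grayscale-ish palette keeps the file viewable while staying indexed
    pal = []
    for i in range(256):
        pal.extend([min(255, i * 80)] * 3)
    img.putpalette(pal)
    img.save(path, format="PNG")
    if sidecar:
        Path(str(path) + ".json").write_text(
            json.dumps({"mode": mask.mode.value, "flipped": mask.flipped})
        )


def read_mask(path: str | Path, mode: AcquisitionMode | None = None,
              palette: Mapping[int, int] | None = None) -> SegmentationMask:
    """Read an indexed or grayscale PNG label mask.

    ``palette`` maps file pixel values to label values; unknown pixel values
    raise :class:`PaletteError`.  ``mode`` may be omitted when a JSON sidecar
    written by :func:`write_mask` is present.
    """
    path = Path(path)
    flipped = False
    if mode is None:
        side = Path(str(path) + ".json")
        if not side.exists():
            raise InvalidGeometryError(
                f"acquisition mode not given and no sidecar found for {path}"
            )
        meta = json.loads(side.read_text())
        mode = AcquisitionMode(meta["mode"])
        flipped = bool(meta.get("flipped", False))
    try:
        with Image.open(path) as img:
            raw = np.asarray(img if img.mode == "P" else img.convert("L"))
    except OSError as exc:  # unreadable file
        raise AngleMechError(f"cannot read mask file {path}: {exc}") from exc
    palette = dict(palette or DEFAULT_PALETTE)
    present = set(np.unique(raw).tolist())
    unknown = present - set(palette)
    if unknown:
        raise PaletteError(f"pixel values {sorted(unknown)} absent from palette")
    labels = np.zeros(raw.shape, dtype=np.uint8)
    for px, lab in palette.items():
        labels[raw == px] = lab
    h, w = labels.shape
    return SegmentationMask(labels=labels, mode=mode,
                            spacing=spacing_for_mode(mode, w, h), flipped=flipped)


# ---------------------------------------------------------------------------
# validation

@dataclass
class ValidationReport:
    """Per-rule pass/fail outcome; failures are enumerated, never fixed."""

    failures: list[str]
    rules: dict[str, bool]

    @property
    def ok(self) -> bool:
        return not self.failures


def _main_components(indicator: np.ndarray) -> tuple[int, np.ndarray]:
    """Number of connected components >= SMALL_OBJECT_PX and their union."""
    lab, n = ndi.label(indicator, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return 0, np.zeros_like(indicator, dtype=bool)
    sizes = np.bincount(lab.ravel())[1:]
    keep = np.flatnonzero(sizes >= SMALL_OBJECT_PX) + 1
    return len(keep), np.isin(lab, keep)


def validate_mask(mask: SegmentationMask) -> ValidationReport:
    """Check structural rules on a tissue-label mask.

    Rules: classes 1-3 each present; each has exactly one connected component
    after removing speckle (< ``SMALL_OBJECT_PX`` px); the iris component is
    8-adjacent to the ciliary-body component.  Exclusion analogue for images
    with incomplete angle structures.
    """
    failures: list[str] = []
    rules: dict[str, bool] = {}
    bad = ~np.isin(mask.labels, [BACKGROUND, IRIS, SCLERA, CILIARY])
    rules["known labels only"] = not bad.any()
    if bad.any():
        failures.append(f"unknown label values {sorted(np.unique(mask.labels[bad]).tolist())}")

    comps: dict[int, np.ndarray] = {}
    for lab in (IRIS, SCLERA, CILIARY):
        name = LABEL_NAMES[lab]
        ind = mask.tissue(lab)
        present = bool(ind.any())
        rules[f"{name} present"] = present
        if not present:
            failures.append(f"missing class {lab} ({name})")
            continue
        n, main = _main_components(ind)
        rules[f"single {name} component"] = n == 1
        if n == 0:
            failures.append(f"{name} has no component >= {SMALL_OBJECT_PX} px")
        elif n > 1:
            failures.append(f"multiple {name} components ({n})")
        comps[lab] = main

    if IRIS in comps and CILIARY in comps:
        dil = ndi.binary_dilation(comps[CILIARY], structure=np.ones((3, 3), dtype=bool))
        adjacent = bool((dil & comps[IRIS]).any())
        rules["iris adjacent to ciliary body"] = adjacent
        if not adjacent:
            failures.append("iris component not 8-adjacent to ciliary-body component")
    return ValidationReport(failures=failures, rules=rules)


# ---------------------------------------------------------------------------
# orientation normalization

def _insertion_zone(mask: SegmentationMask) -> np.ndarray:
    """Boolean raster of iris pixels 8-adjacent to the ciliary body."""
    dil = ndi.binary_dilation(mask.tissue(CILIARY), structure=np.ones((3, 3), dtype=bool))
    return dil & mask.tissue(IRIS)


def normalize_orientation(mask: SegmentationMask) -> SegmentationMask:
    """Mirror horizontally if needed so the angle recess lies on the left.

    The recess side is taken from the iris-root zone (iris pixels adjacent to
    the ciliary body) when available, else from the iris centroid.  Applying
    the function twice is the identity; the ``flipped`` flag records whether
    the raster was mirrored relative to the file on disk.
    """
    h, w = mask.shape
    zone = _insertion_zone(mask)
    if not zone.any():
        zone = mask.tissue(IRIS)
    if not zone.any():
        raise OrientationError("no iris pixels; recess side undeterminable")
    ref_col = float(np.mean(np.nonzero(zone)[1]))
    centre = (w - 1) / 2.0
    if ref_col == centre:
        raise OrientationError("recess side undeterminable: reference column exactly central")
    if ref_col < centre:
        return mask
    return replace(mask, labels=mask.labels[:, ::-1].copy(), flipped=not mask.flipped)


# ---------------------------------------------------------------------------
# subpixel region boundary

def region_boundary(mask: SegmentationMask, tissue: int) -> np.ndarray:
    """Closed subpixel contour of one tissue class at the 0.5 iso-level.

    Marching-squares contour of the tissue indicator; the raster is padded so
    regions touching the image border still yield a closed loop.  Returns an
    (N, 2) float array of (row, col) vertices in consecutive order with the
    first vertex repeated at the end.  With several components the largest
    (by enclosed area) is returned.
    """
    ind = mask.tissue(tissue)
    if not ind.any():
        raise MissingClassError(f"no pixels of class {tissue} ({LABEL_NAMES.get(tissue)})")
    padded = np.pad(ind.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise MissingClassError(f"no contour found for class {tissue}")

    def area(c: np.ndarray) -> float:
        y, x = c[:, 0], c[:, 1]
        return 0.5 * abs(np.dot(y, np.roll(x, -1)) - np.dot(x, np.roll(y, -1)))

    best = max(contours, key=area) - 1.0  # undo padding offset
    if not np.allclose(best[0], best[-1]):
        best = np.vstack([best, best[:1]])
    return best


def contour_arc_length_um(contour: np.ndarray, spacing: PhysicalSpacing) -> float:
    """Total polyline length of a (row, col) contour in micrometres."""
    d = np.diff(contour, axis=0)
    seg = np.hypot(d[:, 1] * spacing.um_per_px_x, d[:, 0] * spacing.um_per_px_y)
    return float(seg.sum())
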