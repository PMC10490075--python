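"""Contour-based seed measurement.

Extracts one outer contour per 8-connected foreground region, keeps the
largest-area contours (which silently discards small noise regions),
fits an enclosing rectangle per seed for length/width, counts foreground
pixels for projected area, and converts everything to millimetres
through a :class:`~seedmorph.calibration.Calibration`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint
from skimage import measure as _skmeasure

from .calibration import Calibration, px2_to_mm2, px_to_mm
from .errors import ContractViolationError, NoSeedFoundError, ShortContourListWarning
from .imaging import (
    BinaryMask,
    MorphologySpec,
    RasterImage,
    ThresholdSpec,
    dilate,
    threshold,
    to_grayscale,
)

__all__ = [
    "Contour",
    "SeedMeasurement",
    "MeasureConfig",
    "find_contours",
    "select_max_area_contour",
    "select_top_n_contours",
    "bounding_rectangle",
    "projected_area_px",
    "measure_seeds",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Contour:
    """Outer boundary of one connected foreground region.

    ``boundary`` is an ordered closed loop of (row, col) coordinates
    traced at sub-pixel precision; ``pixels`` holds the (row, col)
    indices of every pixel in the region; ``area_px`` is the region's
    pixel count.
    """

    boundary: np.ndarray
    area_px: int
    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.area_px < 0:
            raise ContractViolationError("area_px must be >= 0")
        if self.area_px > 1 and len(self.boundary) < 3:
            raise ContractViolationError("boundary of a region with area > 1 needs >= 3 points")


@dataclass(frozen=True)
class SeedMeasurement:
    """One seed's size traits in pixels and (when calibrated) millimetres."""

    length_px: float
    width_px: float
    area_px: int
    aspect_ratio: float
    length_mm: float | None = None
    width_mm: float | None = None
    area_mm2: float | None = None
    centroid_rc: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.length_px >= self.width_px > 0):
            raise ContractViolationError(
                f"require length_px >= width_px > 0; got ({self.length_px}, {self.width_px})"
            )
        if self.area_px <= 0:
            raise ContractViolationError("area_px must be > 0")
        if self.aspect_ratio < 1:
            raise ContractViolationError("aspect_ratio must be >= 1")


@dataclass(frozen=True)
class MeasureConfig:
    """Tunable pipeline parameters.

    Defaults follow the reference workflow: a 140/255 global threshold
    for size traits, a stricter 170/255 threshold for projected area and
    counting, dilation off for measurement and on for counting.
    """

    size_threshold: ThresholdSpec = ThresholdSpec(140, 255)
    area_threshold: ThresholdSpec = ThresholdSpec(170, 255)
    n_seeds: int = 1
    morphology: MorphologySpec = MorphologySpec(3, 1)
    min_contour_area_px: int = 25
    dilate_before_measure: bool = False
    dilate_before_count: bool = True
    rotated_rect: bool = True

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ContractViolationError("n_seeds must be >= 1")
        if self.min_contour_area_px < 0:
            raise ContractViolationError("min_contour_area_px must be >= 0")


def find_contours(mask: BinaryMask) -> list[Contour]:
    """One :class:`Contour` per 8-connected foreground region.

    Outer boundaries only; interior holes are ignored.  Regions are
    returned in raster-scan order of first occurrence.
    """
    fg = mask.foreground()
    labelled, n = ndimage.label(fg, structure=_EIGHT_CONNECTED)
    contours: list[Contour] = []
    for idx, sl in enumerate(ndimage.find_objects(labelled), start=1):
        sub = labelled[sl] == idx
        area = int(sub.sum())
        padded = np.pad(sub.astype(float), 1)
        loops = _skmeasure.find_contours(padded, 0.5)
        boundary = max(loops, key=len)  # outer loop is the longest
        boundary = boundary + np.array([sl[0].start - 1, sl[1].start - 1])
        pixels = np.argwhere(sub) + np.array([sl[0].start, sl[1].start])
        contours.append(Contour(boundary=boundary, area_px=area, pixels=pixels))
    return contours


def select_max_area_contour(contours: list[Contour]) -> Contour:
    """The largest-area contour; ties go to the earliest in list order."""
    if not contours:
        raise NoSeedFoundError("no contours to select from")
    return max(contours, key=lambda c: c.area_px)  # max() keeps first on ties


def select_top_n_contours(contours: list[Contour], n: int) -> list[Contour]:
    """The ``n`` largest contours by area, descending.

    If fewer than ``n`` exist, all are returned and a
    :class:`ShortContourListWarning` is emitted.
    """
    if n < 1:
        raise ContractViolationError("n must be >= 1")
    ranked = sorted(contours, key=lambda c: -c.area_px)
    if len(ranked) < n:
        warnings.warn(
            f"requested {n} contours but only {len(ranked)} found",
            ShortContourListWarning,
            stacklevel=2,
        )
    return ranked[:n]


def _border_pixels(c: Contour) -> np.ndarray:
    """Pixels of the region that touch the background (or the frame edge)."""
    rmin, cmin = c.pixels.min(axis=0)
    rmax, cmax = c.pixels.max(axis=0)
    sub = np.zeros((rmax - rmin + 1, cmax - cmin + 1), dtype=bool)
    sub[c.pixels[:, 0] - rmin, c.pixels[:, 1] - cmin] = True
    interior = ndimage.binary_erosion(sub, structure=_EIGHT_CONNECTED, border_value=0)
    border = np.argwhere(sub & ~interior)
    return border + np.array([rmin, cmin])


def _min_area_rect_sides(pts: np.ndarray) -> tuple[float, float]:
    """Side lengths of the minimum-area rotated rectangle of ``pts``."""
    rect = MultiPoint([(float(x), float(y)) for x, y in pts]).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # collinear pixels degenerate to a line
        length = float(rect.length) if rect.geom_type == "LineString" else 0.0
        return (length, 0.0)
    x, y = rect.exterior.coords.xy
    s1 = math.hypot(x[1] - x[0], y[1] - y[0])
    s2 = math.hypot(x[2] - x[1], y[2] - y[1])
    return (max(s1, s2), min(s1, s2))


def _principal_axis_sides(c: Contour, border: np.ndarray) -> tuple[float, float]:
    """Extent of the border along the region's principal axes.

    The orientation comes from the central second moments of the full
    pixel set, which averages out boundary discretization noise that
    destabilizes a pure minimum-area fit on near-round regions.
    """
    pts = c.pixels.astype(float)
    mean = pts.mean(axis=0)
    d = pts - mean
    mu20, mu02 = (d**2).mean(axis=0)
    mu11 = (d[:, 0] * d[:, 1]).mean()
    theta = 0.5 * math.atan2(2 * mu11, mu20 - mu02)
    axis = np.array([math.cos(theta), math.sin(theta)])
    perp = np.array([-axis[1], axis[0]])
    b = border - mean
    u = b @ axis
    v = b @ perp
    return (float(u.max() - u.min()), float(v.max() - v.min()))


def bounding_rectangle(c: Contour, rotated: bool = True) -> tuple[float, float]:
    """Enclosing rectangle of a contour as ``(length_px, width_px)``.

    ``rotated=True`` (default) fits a rotated rectangle invariant under
    image-plane rotation of the region up to discretization error:
    oriented by the region's principal axes, falling back to the
    minimum-area rectangle when the moment orientation is degenerate
    (e.g. a tilted square, whose second moments are isotropic).
    ``rotated=False`` uses the axis-aligned box.  Pixel centres
    under-reach the true silhouette edge, so half a pixel is added to
    each side fitted through them.
    """
    if c.area_px <= 0:
        raise ContractViolationError("contour must enclose at least one pixel")
    if c.area_px == 1:
        return (1.0, 1.0)
    if not rotated:
        rmin, cmin = c.pixels.min(axis=0)
        rmax, cmax = c.pixels.max(axis=0)
        h, w = float(rmax - rmin + 1), float(cmax - cmin + 1)
        return (max(h, w), min(h, w))
    border = _border_pixels(c).astype(float)
    pa, pb = _principal_axis_sides(c, border)
    ma, mb = _min_area_rect_sides(border)
    # moment orientation degenerate -> its rect is much bigger than minimal
    if ma * mb > 0 and pa * pb > 1.05 * ma * mb:
        s1, s2 = ma, mb
    else:
        s1, s2 = pa, pb
    return (max(s1, s2) + 0.5, max(min(s1, s2) + 0.5, 1.0))


def projected_area_px(mask: BinaryMask) -> int:
    """Exact count of foreground pixels in the mask."""
    return int(np.count_nonzero(mask.pixels))


def _filled_region_mask(c: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the contour's interior (holes filled) on ``shape``."""
    out = np.zeros(shape, dtype=bool)
    out[c.pixels[:, 0], c.pixels[:, 1]] = True
    return ndimage.binary_fill_holes(out)


def measure_seeds(
    img: RasterImage,
    cfg: MeasureConfig = MeasureConfig(),
    cal: Calibration | None = None,
) -> list[SeedMeasurement]:
    """Measure the ``cfg.n_seeds`` largest seeds in an image.

    Pipeline: grayscale -> optional dilation -> size threshold ->
    contours -> noise-floor filter -> top-n by area -> per-seed
    rectangle.  Projected area is counted per seed from the pixels of
    the (stricter) area-threshold mask that fall inside that seed's
    contour interior.  Millimetre fields are filled only when ``cal``
    is given.

    Raises :class:`NoSeedFoundError` when no contour reaches
    ``cfg.min_contour_area_px``.
    """
    gray = to_grayscale(img)
    size_src = dilate(gray, cfg.morphology) if cfg.dilate_before_measure else gray
    size_mask = threshold(size_src, cfg.size_threshold)
    area_mask = threshold(gray, cfg.area_threshold)

    contours = [
        c for c in find_contours(size_mask) if c.area_px >= cfg.min_contour_area_px
    ]
    if not contours:
        raise NoSeedFoundError(
            f"no contour with area >= {cfg.min_contour_area_px} px found"
        )
    selected = select_top_n_contours(contours, cfg.n_seeds)

    area_fg = area_mask.foreground()
    shape = (img.height, img.width)
    results: list[SeedMeasurement] = []
    for c in selected:
        length_px, width_px = bounding_rectangle(c, rotated=cfg.rotated_rect)
        interior = _filled_region_mask(c, shape)
        seed_area = int(np.count_nonzero(area_fg & interior))
        kwargs = {}
        if cal is not None:
            kwargs = {
                "length_mm": px_to_mm(length_px, cal),
                "width_mm": px_to_mm(width_px, cal),
                "area_mm2": px2_to_mm2(seed_area, cal),
            }
        centroid = tuple(c.pixels.mean(axis=0).tolist())
        results.append(
            SeedMeasurement(
                length_px=length_px,
                width_px=width_px,
                area_px=seed_area,
                aspect_ratio=length_px / width_px,
                centroid_rc=centroid,
                **kwargs,
            )
        )
    return results
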