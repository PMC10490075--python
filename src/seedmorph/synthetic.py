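"""Ground-truth synthetic scene generator.

Renders seed-like shapes (disks, ellipses, rectangles) of known
millimetre dimensions at a chosen pixels-per-mm scale onto a
near-black background, optionally sprinkled with small speckle noise.
Every scene carries retrievable analytic ground truth, so the whole
measurement pipeline is testable without any photographs.

Rasterization is hard-edged by default (a pixel is foreground iff its
centre lies inside the shape) so pixel-count oracles are exact; an
anti-aliased mode exists for robustness testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import SceneConstructionError
from .imaging import RasterImage
from .morphometry import SeedMeasurement

__all__ = [
    "ShapeSpec",
    "SyntheticScene",
    "render",
    "ground_truth",
    "make_trial_grid",
    "random_scene",
    "overlapping_pair_scene",
    "add_speckles",
]

_KINDS = ("disk", "ellipse", "rectangle")


@dataclass(frozen=True)
class ShapeSpec:
    """One seed-like shape with analytic dimensions.

    ``axes_mm`` are full axis lengths (major, minor); for a disk they
    are equal and act as the diameter.  ``center`` is in pixel (row,
    col) coordinates.  Intensity defaults to 220, comfortably above
    both the 140 and 170 global thresholds.
    """

    kind: str
    center: tuple[float, float]
    axes_mm: tuple[float, float]
    rotation_deg: float = 0.0
    intensity: int = 220

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SceneConstructionError(f"unknown shape kind: {self.kind!r}")
        major, minor = self.axes_mm
        if not (major >= minor > 0):
            raise SceneConstructionError("axes_mm must satisfy major >= minor > 0")
        if not (0 < self.intensity <= 255):
            raise SceneConstructionError("intensity must lie in (0, 255]")

    def area_mm2(self) -> float:
        """Analytic area: π·a·b/4 for ellipse/disk, a·b for rectangle."""
        major, minor = self.axes_mm
        if self.kind == "rectangle":
            return major * minor
        return math.pi * major * minor / 4.0


@dataclass(frozen=True)
class SyntheticScene:
    """A renderable scene with known ground truth."""

    shapes: tuple[ShapeSpec, ...]
    px_per_mm: float
    image_size: tuple[int, int]
    background_intensity: int = 10
    noise_speckles: int = 0
    # default radii keep speckles below a 25 px noise floor even after
    # one 3x3 dilation (worst case ~21 px)
    speckle_radius_px: tuple[float, float] = (0.5, 1.2)
    speckle_intensity: int = 220
    rng_seed: int = 0
    allow_overlap: bool = False
    anti_alias: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "shapes", tuple(self.shapes))
        if self.px_per_mm <= 0:
            raise SceneConstructionError("px_per_mm must be > 0")
        rows, cols = self.image_size
        if rows < 1 or cols < 1:
            raise SceneConstructionError("image_size must be positive")
        if not self.allow_overlap:
            for s in self.shapes:
                half = s.axes_mm[0] * self.px_per_mm / 2.0
                r, c = s.center
                if (r - half < 0 or c - half < 0
                        or r + half > rows - 1 or c + half > cols - 1):
                    raise SceneConstructionError(
                        f"shape at {s.center} does not fit inside {self.image_size}"
                    )


def _shape_inside(shape: ShapeSpec, px_per_mm: float, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    """Boolean membership of pixel centres (rr, cc) in the shape."""
    a = shape.axes_mm[0] * px_per_mm / 2.0
    b = shape.axes_mm[1] * px_per_mm / 2.0
    dr = rr - shape.center[0]
    dc = cc - shape.center[1]
    th = math.radians(shape.rotation_deg)
    u = dc * math.cos(th) + dr * math.sin(th)
    v = -dc * math.sin(th) + dr * math.cos(th)
    if shape.kind == "rectangle":
        return (np.abs(u) <= a) & (np.abs(v) <= b)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _paint(canvas: np.ndarray, shape: ShapeSpec, px_per_mm: float, anti_alias: bool) -> None:
    rows, cols = canvas.shape
    half = shape.axes_mm[0] * px_per_mm / 2.0 + 2
    r0 = max(int(shape.center[0] - half), 0)
    r1 = min(int(shape.center[0] + half) + 1, rows)
    c0 = max(int(shape.center[1] - half), 0)
    c1 = min(int(shape.center[1] + half) + 1, cols)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1, dtype=float),
                         np.arange(c0, c1, dtype=float), indexing="ij")
    if not anti_alias:
        inside = _shape_inside(shape, px_per_mm, rr, cc)
        patch = canvas[r0:r1, c0:c1]
        patch[inside] = shape.intensity
        return
    # 3x3 subsampled coverage blend
    cover = np.zeros(rr.shape, dtype=float)
    offsets = (-1 / 3, 0.0, 1 / 3)
    for dr in offsets:
        for dc in offsets:
            cover += _shape_inside(shape, px_per_mm, rr + dr, cc + dc)
    cover /= 9.0
    patch = canvas[r0:r1, c0:c1]
    blended = np.round(patch + cover * (shape.intensity - patch))
    canvas[r0:r1, c0:c1] = np.clip(blended, 0, 255)


def render(scene: SyntheticScene) -> RasterImage:
    """Rasterize a scene to an RGB image (R = G = B).

    Deterministic for a fixed ``rng_seed``: two calls produce identical
    pixel grids.  Speckles are placed on background only, clear of all
    shapes, so they never merge with a seed.
    """
    rows, cols = scene.image_size
    canvas = np.full((rows, cols), scene.background_intensity, dtype=float)
    for shape in scene.shapes:
        _paint(canvas, shape, scene.px_per_mm, scene.anti_alias)
    if scene.noise_speckles > 0:
        shape_fg = canvas > scene.background_intensity
        rng = np.random.default_rng(scene.rng_seed)
        _sprinkle(canvas, shape_fg, scene, rng)
    gray = canvas.astype(np.uint8)
    return RasterImage(np.stack([gray, gray, gray], axis=-1))


def _sprinkle(canvas: np.ndarray, shape_fg: np.ndarray, scene: SyntheticScene,
              rng: np.random.Generator) -> None:
    """Place speckle disks on background, rejected if they would touch a shape."""
    rows, cols = canvas.shape
    rmin, rmax = scene.speckle_radius_px
    placed = 0
    attempts = 0
    while placed < scene.noise_speckles and attempts < scene.noise_speckles * 200:
        attempts += 1
        radius = rng.uniform(rmin, rmax)
        r = rng.uniform(radius + 1, rows - radius - 2)
        c = rng.uniform(radius + 1, cols - radius - 2)
        pad = int(radius) + 4  # keep a >=3 px gap so dilation cannot bridge
        r0, r1 = int(r) - pad, int(r) + pad + 1
        c0, c1 = int(c) - pad, int(c) + pad + 1
        if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
            continue
        if shape_fg[r0:r1, c0:c1].any():
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1, dtype=float),
                             np.arange(c0, c1, dtype=float), indexing="ij")
        disk = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
        if not disk.any():
            continue
        canvas[r0:r1, c0:c1][disk] = scene.speckle_intensity
        shape_fg[r0:r1, c0:c1] |= disk
        placed += 1


def ground_truth(scene: SyntheticScene) -> list[SeedMeasurement]:
    """Analytic measurements per shape, area-descending to match the
    measurement module's selection order."""
    out = []
    ppm = scene.px_per_mm
    for s in scene.shapes:
        major, minor = s.axes_mm
        area_mm2 = s.area_mm2()
        area_px = max(int(round(area_mm2 * ppm**2)), 1)
        out.append(
            SeedMeasurement(
                length_px=major * ppm,
                width_px=minor * ppm,
                area_px=area_px,
                aspect_ratio=major / minor,
                length_mm=major,
                width_mm=minor,
                area_mm2=area_mm2,
                centroid_rc=s.center,
            )
        )
    return sorted(out, key=lambda m: -m.area_px)


def random_scene(
    rng: np.random.Generator,
    n_shapes: int = 1,
    sizes_mm_range: tuple[float, float] = (4.0, 9.0),
    px_per_mm: float = 25.0,
    kinds: tuple[str, ...] = ("ellipse", "ellipse", "ellipse", "disk"),
    noise_speckles: int = 0,
    margin_px: int = 12,
    intensity: int = 220,
) -> SyntheticScene:
    """One scene of ``n_shapes`` disjoint shapes placed on a jittered grid.

    Axes are drawn uniformly from ``sizes_mm_range``; grid placement
    guarantees shapes never touch.
    """
    cell = int(math.ceil(sizes_mm_range[1] * px_per_mm)) + 2 * margin_px
    ncols = max(int(math.ceil(math.sqrt(n_shapes))), 1)
    nrows = max(int(math.ceil(n_shapes / ncols)), 1)
    shapes = []
    for i in range(n_shapes):
        gr, gc = divmod(i, ncols)
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind == "disk":
            d = float(rng.uniform(*sizes_mm_range))
            axes = (d, d)
        else:
            a, b = rng.uniform(*sizes_mm_range, size=2)
            axes = (float(max(a, b)), float(min(a, b)))
        jitter_r, jitter_c = rng.uniform(-margin_px / 2, margin_px / 2, size=2)
        center = (gr * cell + cell / 2 + jitter_r, gc * cell + cell / 2 + jitter_c)
        shapes.append(
            ShapeSpec(
                kind=kind,
                center=center,
                axes_mm=axes,
                rotation_deg=float(rng.uniform(0, 180)),
                intensity=intensity,
            )
        )
    size = (nrows * cell, ncols * cell)
    return SyntheticScene(
        shapes=tuple(shapes),
        px_per_mm=px_per_mm,
        image_size=size,
        noise_speckles=noise_speckles,
        rng_seed=int(rng.integers(2**31)),
    )


def make_trial_grid(
    n_scenes: int,
    sizes_mm_range: tuple[float, float] = (4.0, 9.0),
    px_per_mm: float = 25.0,
    rng_seed: int = 0,
    n_shapes: int = 1,
) -> list[SyntheticScene]:
    """Reproducible batch of random scenes for the acceptance suite."""
    if n_scenes < 1:
        raise SceneConstructionError("n_scenes must be >= 1")
    rng = np.random.default_rng(rng_seed)
    return [
        random_scene(rng, n_shapes=n_shapes, sizes_mm_range=sizes_mm_range,
                     px_per_mm=px_per_mm)
        for _ in range(n_scenes)
    ]


def overlapping_pair_scene(
    overlap_fraction: float = 0.3,
    diameter_mm: float = 6.0,
    px_per_mm: float = 25.0,
    intensity: int = 220,
) -> SyntheticScene:
    """Two equal disks whose centres are ``2r·(1 − overlap_fraction)``
    apart, i.e. overlapping; used to pin the merged-count limitation."""
    r_px = diameter_mm * px_per_mm / 2.0
    gap = 2 * r_px * (1.0 - overlap_fraction)
    side = int(4 * r_px + gap) + 40
    mid = side / 2.0
    shapes = (
        ShapeSpec("disk", (mid, mid - gap / 2), (diameter_mm, diameter_mm), intensity=intensity),
        ShapeSpec("disk", (mid, mid + gap / 2), (diameter_mm, diameter_mm), intensity=intensity),
    )
    return SyntheticScene(shapes=shapes, px_per_mm=px_per_mm,
                          image_size=(side, side), allow_overlap=True)


def add_speckles(scene: SyntheticScene, n: int, rng_seed: int | None = None,
                 radius_px: tuple[float, float] = (0.5, 1.2)) -> SyntheticScene:
    """Copy of ``scene`` with ``n`` extra noise speckles."""
    return replace(
        scene,
        noise_speckles=scene.noise_speckles + n,
        speckle_radius_px=radius_px,
        rng_seed=scene.rng_seed if rng_seed is None else rng_seed,
    )
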