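"""Seed counting.

Chain: grayscale -> dilation (default on) -> strict 170/255 threshold
-> contour extraction -> count of contours above the noise floor.
Touching or overlapping seeds merge into one contour and are counted as
one; that limitation is deliberate and test-pinned, not accidental.
"""

from __future__ import annotations

from dataclasses import dataclass

from .imaging import RasterImage, dilate, threshold, to_grayscale
from .morphometry import MeasureConfig, find_contours

__all__ = ["CountResult", "count_seeds"]


@dataclass(frozen=True)
class CountResult:
    """Outcome of counting one image."""

    n_seeds: int
    contour_areas_px: tuple[int, ...]
    n_rejected_noise: int

    def __post_init__(self) -> None:
        assert self.n_seeds == len(self.contour_areas_px)


def count_seeds(img: RasterImage, cfg: MeasureConfig = MeasureConfig()) -> CountResult:
    """Count seeds in ``img``.

    Regions whose area falls below ``cfg.min_contour_area_px`` are
    rejected as noise and tallied separately.  Zero seeds is a valid
    result, not an error.  Deterministic for fixed input and config.
    """
    gray = to_grayscale(img)
    src = dilate(gray, cfg.morphology) if cfg.dilate_before_count else gray
    mask = threshold(src, cfg.area_threshold)
    contours = find_contours(mask)
    retained = [c.area_px for c in contours if c.area_px >= cfg.min_contour_area_px]
    rejected = len(contours) - len(retained)
    return CountResult(
        n_seeds=len(retained),
        contour_areas_px=tuple(retained),
        n_rejected_noise=rejected,
    )
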