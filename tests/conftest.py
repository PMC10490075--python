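import numpy as np
import pytest

from seedmorph.imaging import BinaryMask, RasterImage
from seedmorph.synthetic import ShapeSpec, SyntheticScene, render


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def single_ellipse_scene():
    """One 6x4 mm ellipse at 25 px/mm (axes 150x100 px), axis-aligned."""
    return SyntheticScene(
        shapes=(ShapeSpec("ellipse", (150.0, 150.0), (6.0, 4.0)),),
        px_per_mm=25.0,
        image_size=(300, 300),
    )


@pytest.fixture
def single_ellipse_image(single_ellipse_scene):
    return render(single_ellipse_scene)


def random_mask(rng, shape=(64, 64), p=0.3, maxval=255) -> BinaryMask:
    """Random two-valued mask for oracle-equivalence tests."""
    fg = rng.random(shape) < p
    return BinaryMask(np.where(fg, maxval, 0).astype(np.uint8), maxval=maxval)


def gray_image(arr) -> RasterImage:
    return RasterImage(np.asarray(arr, dtype=np.uint8))


def brute_force_label_count(fg: np.ndarray) -> int:
    """Independent 8-connected component count via BFS flood fill."""
    fg = np.asarray(fg, dtype=bool)
    seen = np.zeros_like(fg)
    rows, cols = fg.shape
    count = 0
    for r0 in range(rows):
        for c0 in range(cols):
            if fg[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < rows and 0 <= cc < cols
                                    and fg[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return count


def brute_force_dilate(arr: np.ndarray, k: int) -> np.ndarray:
    """Sliding-window maximum with zero padding, straight from the definition."""
    arr = np.asarray(arr)
    rows, cols = arr.shape
    half = k // 2
    out = np.zeros_like(arr)
    for r in range(rows):
        for c in range(cols):
            best = 0
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols:
                        best = max(best, int(arr[rr, cc]))
            out[r, c] = best
    return out
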