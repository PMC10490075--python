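"""Raster loading and the preprocessing chain.

Grayscale conversion, grayscale dilation, and global binary thresholding --
the three primitives every downstream measurement and counting stage
consumes.  Images are carried as 8-bit numpy arrays wrapped in small
dataclasses that enforce the domain invariants.

Conventions
-----------
* Pixels are addressed 0-based, row-major, as ``(row, col)``; a pixel
  occupies the unit square centred on its index.
* Colour images are stored channel-last in (R, G, B) order regardless of
  the decoding library's native convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from .errors import ContractViolationError, ImageFormatError

__all__ = [
    "RasterImage",
    "BinaryMask",
    "ThresholdSpec",
    "MorphologySpec",
    "load_image",
    "to_grayscale",
    "dilate",
    "threshold",
]

# ITU-R BT.601 luminance weights used for RGB -> gray conversion.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class RasterImage:
    """An 8-bit grayscale or RGB pixel grid.

    Parameters
    ----------
    pixels : numpy.ndarray
        ``(H, W)`` for grayscale or ``(H, W, 3)`` for RGB; dtype uint8.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            pass
        elif px.ndim == 3 and px.shape[2] == 3:
            pass
        else:
            raise ContractViolationError(
                f"pixels must be (H, W) or (H, W, 3); got shape {px.shape}"
            )
        if px.size == 0:
            raise ContractViolationError("image must have at least one pixel")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ContractViolationError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3


@dataclass(frozen=True)
class ThresholdSpec:
    """Global threshold: intensity > ``lower`` maps to ``maxval``, else 0."""

    lower: int = 140
    maxval: int = 255

    def __post_init__(self) -> None:
        if not (0 <= self.lower < self.maxval <= 255):
            raise ContractViolationError(
                f"require 0 <= lower < maxval <= 255; got ({self.lower}, {self.maxval})"
            )


@dataclass(frozen=True)
class MorphologySpec:
    """Square structuring element of odd side ``kernel_shape``, applied
    ``iterations`` times (0 = no-op)."""

    kernel_shape: int = 3
    iterations: int = 1

    def __post_init__(self) -> None:
        if self.kernel_shape < 1 or self.kernel_shape % 2 == 0:
            raise ContractViolationError("kernel_shape must be an odd integer >= 1")
        if self.iterations < 0:
            raise ContractViolationError("iterations must be >= 0")


@dataclass(frozen=True)
class BinaryMask:
    """A two-valued foreground mask: pixels are either 0 or ``maxval``."""

    pixels: np.ndarray
    maxval: int = 255

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ContractViolationError("mask must be 2-D")
        if not (1 <= self.maxval <= 255):
            raise ContractViolationError("maxval must lie in [1, 255]")
        px = px.astype(np.uint8, copy=False)
        bad = (px != 0) & (px != self.maxval)
        if bad.any():
            raise ContractViolationError(
                f"mask contains values other than 0 and {self.maxval}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def foreground(self) -> np.ndarray:
        """Boolean view of the foreground."""
        return self.pixels != 0


def load_image(path: str | os.PathLike) -> RasterImage:
    """Load a PNG/JPEG/TIFF raster from ``path``.

    Colour files come back as 3-channel (R, G, B); single-band files as
    1-channel.  Lossless formats round-trip bit-exact.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ImageFormatError
        If the bytes cannot be decoded as a supported raster.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            if im.mode == "L":
                arr = np.asarray(im, dtype=np.uint8)
            elif im.mode == "RGB":
                arr = np.asarray(im, dtype=np.uint8)
            elif im.mode in ("1", "I", "I;16", "P", "LA"):
                arr = np.asarray(im.convert("L"), dtype=np.uint8)
            else:  # RGBA, CMYK, ...
                arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"cannot decode {path!r} as an image") from exc
    return RasterImage(arr)


def save_image(img: RasterImage, path: str | os.PathLike) -> None:
    """Write ``img`` to ``path``; format chosen from the file extension."""
    Image.fromarray(img.pixels).save(path)


def to_grayscale(img: RasterImage) -> RasterImage:
    """Convert to 1-channel using BT.601 luminance weights.

    Weighted sum 0.299 R + 0.587 G + 0.114 B, rounded half-up to an
    integer in [0, 255].  A grayscale input is returned unchanged.
    """
    if img.channels == 1:
        return img
    luma = img.pixels.astype(np.float64) @ _LUMA_WEIGHTS
    return RasterImage(np.floor(luma + 0.5).astype(np.uint8))


def dilate(img: RasterImage, spec: MorphologySpec = MorphologySpec()) -> RasterImage:
    """Grayscale dilation: neighbourhood maximum over a square kernel.

    Applied ``spec.iterations`` times; 0 iterations returns the input
    unchanged.  Output >= input pixel-wise (extensivity).
    """
    if img.channels != 1:
        raise ContractViolationError("dilate requires a 1-channel image")
    if spec.iterations == 0:
        return img
    out = img.pixels
    k = spec.kernel_shape
    for _ in range(spec.iterations):
        out = ndimage.grey_dilation(out, size=(k, k), mode="constant", cval=0)
    return RasterImage(out)


def threshold(img: RasterImage, spec: ThresholdSpec) -> BinaryMask:
    """Global binary threshold: intensity strictly greater than
    ``spec.lower`` becomes ``spec.maxval``, everything else 0."""
    if img.channels != 1:
        raise ContractViolationError("threshold requires a 1-channel image")
    out = np.where(img.pixels > spec.lower, spec.maxval, 0).astype(np.uint8)
    return BinaryMask(out, maxval=spec.maxval)
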