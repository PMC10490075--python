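"""Pixel-to-millimetre calibration.

A scale factor (pixels per mm) is derived from two image points a known
physical distance apart -- typically two ruler ticks 10 mm apart
photographed at the same camera geometry as the seed images.  The
calibration can be persisted to a small JSON file so one ruler shot
serves a whole imaging session.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import os
from dataclasses import dataclass

from .errors import InvalidCalibrationError

__all__ = [
    "Calibration",
    "pixel_distance",
    "make_calibration",
    "px_to_mm",
    "px2_to_mm2",
    "save_calibration",
    "load_calibration",
]

Point = tuple[float, float]


@dataclass(frozen=True)
class Calibration:
    """Pixels-per-millimetre scale, optionally with its source points."""

    px_per_mm: float
    source_points: tuple[Point, Point] | None = None
    known_distance_mm: float | None = None

    def __post_init__(self) -> None:
        if not (self.px_per_mm > 0 and math.isfinite(self.px_per_mm)):
            raise InvalidCalibrationError(
                f"px_per_mm must be finite and > 0; got {self.px_per_mm}"
            )


def pixel_distance(p1: Point, p2: Point) -> float:
    """Euclidean distance between two (row, col) points, in pixels."""
    return math.hypot(p1[0] - p2[0], p1[1] - p2[1])


def make_calibration(p1: Point, p2: Point, known_mm: float) -> Calibration:
    """Build a calibration from two points ``known_mm`` apart.

    Raises :class:`InvalidCalibrationError` for coincident points or a
    non-positive physical distance.
    """
    if known_mm <= 0:
        raise InvalidCalibrationError(f"known distance must be > 0 mm; got {known_mm}")
    d = pixel_distance(p1, p2)
    if d == 0:
        raise InvalidCalibrationError("calibration points are coincident")
    return Calibration(
        px_per_mm=d / known_mm,
        source_points=(tuple(p1), tuple(p2)),
        known_distance_mm=float(known_mm),
    )


def px_to_mm(v_px: float, cal: Calibration) -> float:
    """Convert a pixel length to millimetres."""
    return v_px / cal.px_per_mm


def px2_to_mm2(a_px: float, cal: Calibration) -> float:
    """Convert a pixel area to square millimetres."""
    return a_px / cal.px_per_mm**2


def save_calibration(cal: Calibration, path: str | os.PathLike) -> None:
    """Persist a calibration as JSON (scale, provenance points, date)."""
    payload = {
        "px_per_mm": cal.px_per_mm,
        "source_points": cal.source_points,
        "known_distance_mm": cal.known_distance_mm,
        "created": _dt.date.today().isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_calibration(path: str | os.PathLike) -> Calibration:
    """Read a calibration previously written by :func:`save_calibration`."""
    with open(path) as fh:
        payload = json.load(fh)
    pts = payload.get("source_points")
    if pts is not None:
        pts = (tuple(pts[0]), tuple(pts[1]))
    return Calibration(
        px_per_mm=float(payload["px_per_mm"]),
        source_points=pts,
        known_distance_mm=payload.get("known_distance_mm"),
    )
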