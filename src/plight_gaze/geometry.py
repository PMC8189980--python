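"""Screen geometry and visual-angle <-> pixel conversions.

The viewing setup is a participant seated at a fixed distance from a flat
screen of known resolution and physical size.  Stimulus coordinates are kept
in screen-centered degrees of visual angle; gaze samples are in pixels with
the origin at the top-left corner (screen convention, y grows downward).
Conversion uses the linear small-angle convention: one degree subtends
``distance * tan(1 deg)`` centimetres regardless of eccentricity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScreenGeometry",
    "degrees_to_pixels",
    "pixels_to_degrees",
    "deg_to_px_xy",
    "px_to_deg_xy",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display and viewing-distance parameters.

    Defaults describe a 23-inch 1920x1080 monitor viewed from 60 cm.
    """

    width_px: int = 1920
    height_px: int = 1080
    diagonal_in: float = 23.0
    distance_cm: float = 60.0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) <= 0:
            raise ValueError("screen resolution must be positive")
        if self.diagonal_in <= 0 or self.distance_cm <= 0:
            raise ValueError("diagonal and viewing distance must be positive")

    @property
    def cm_per_px(self) -> float:
        diag_px = math.hypot(self.width_px, self.height_px)
        return self.diagonal_in * 2.54 / diag_px

    @property
    def pixels_per_degree(self) -> float:
        cm_per_deg = self.distance_cm * math.tan(math.radians(1.0))
        return cm_per_deg / self.cm_per_px

    @property
    def width_deg(self) -> float:
        return self.width_px / self.pixels_per_degree

    @property
    def height_deg(self) -> float:
        return self.height_px / self.pixels_per_degree

    @property
    def center_px(self) -> tuple[float, float]:
        return self.width_px / 2.0, self.height_px / 2.0


def degrees_to_pixels(deg, geometry: ScreenGeometry):
    """Convert a visual-angle extent (degrees) to a pixel extent."""
    return np.asarray(deg, dtype=float) * geometry.pixels_per_degree


def pixels_to_degrees(px, geometry: ScreenGeometry):
    """Inverse of :func:`degrees_to_pixels`."""
    return np.asarray(px, dtype=float) / geometry.pixels_per_degree


def deg_to_px_xy(x_deg, y_deg, geometry: ScreenGeometry):
    """Map screen-centered degree coordinates to pixel coordinates.

    Positive y in degrees points up; pixel y grows downward.
    """
    cx, cy = geometry.center_px
    ppd = geometry.pixels_per_degree
    return (
        cx + np.asarray(x_deg, dtype=float) * ppd,
        cy - np.asarray(y_deg, dtype=float) * ppd,
    )


def px_to_deg_xy(x_px, y_px, geometry: ScreenGeometry):
    cx, cy = geometry.center_px
    ppd = geometry.pixels_per_degree
    return (
        (np.asarray(x_px, dtype=float) - cx) / ppd,
        (cy - np.asarray(y_px, dtype=float)) / ppd,
    )
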