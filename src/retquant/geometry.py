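"""Planar window geometry shared by all modules.

All coordinates are microns in the flat-mount plane, origin at the top-left
pixel center, x rightward, y downward. Rectangles are half-open:
``[x0, x1) x [y0, y1)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = ["Rect", "Disc", "Window", "SquareROI"]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned half-open rectangle in microns."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("degenerate rectangle: requires x1 > x0 and y1 > y0")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area_um2(self) -> float:
        return self.width * self.height

    @property
    def area_mm2(self) -> float:
        return self.area_um2 * 1e-6

    def contains(self, x, y, margin: float = 0.0):
        """Membership test; ``margin > 0`` shrinks the rectangle on all sides."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= self.x0 + margin)
            & (x < self.x1 - margin)
            & (y >= self.y0 + margin)
            & (y < self.y1 - margin)
        )

    def shrunk(self, margin: float) -> "Rect":
        return Rect(self.x0 + margin, self.y0 + margin, self.x1 - margin, self.y1 - margin)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))


@dataclass(frozen=True)
class Disc:
    """Closed disc in microns (e.g. a whole-retina outline idealized)."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("disc radius must be positive")

    @property
    def area_um2(self) -> float:
        return math.pi * self.radius**2

    @property
    def area_mm2(self) -> float:
        return self.area_um2 * 1e-6

    def contains(self, x, y, margin: float = 0.0):
        x = np.asarray(x)
        y = np.asarray(y)
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= (self.radius - margin) ** 2

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)


Window = Union[Rect, Disc]


@dataclass(frozen=True)
class SquareROI:
    """Square region of interest, half-open ``[x, x+side) x [y, y+side)``."""

    x_um: float
    y_um: float
    side_um: float

    def __post_init__(self) -> None:
        if not self.side_um > 0:
            raise ValueError("ROI side must be positive")

    @property
    def rect(self) -> Rect:
        return Rect(self.x_um, self.y_um, self.x_um + self.side_um, self.y_um + self.side_um)

    @property
    def area_mm2(self) -> float:
        return self.side_um**2 * 1e-6
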