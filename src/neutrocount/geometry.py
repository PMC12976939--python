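"""Axis-aligned bounding boxes and intersection-over-union.

Pixel boxes use half-open integer-friendly intervals ``[x0, x1) x [y0, y1)``
with the origin at the image's top-left corner, so areas of integer boxes are
exact and a grid of boxes tiles an image without gaps or double counting.
Normalized boxes follow the common detection-label convention: class index
followed by centre and size as fractions of the image dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

_EPS = 1e-9


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Box:
    """Rectangle in pixel coordinates, ``[x0, x1) x [y0, y1)``, positive area."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValidationError(
                f"degenerate box ({self.x0}, {self.y0}, {self.x1}, {self.y1}): "
                "requires x1 > x0 and y1 > y0"
            )

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def translate(self, dx: float, dy: float) -> "Box":
        return Box(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)

    def intersection_area(self, other: "Box") -> float:
        iw = min(self.x1, other.x1) - max(self.x0, other.x0)
        ih = min(self.y1, other.y1) - max(self.y0, other.y0)
        if iw <= 0.0 or ih <= 0.0:
            return 0.0
        return iw * ih

    def contains_point(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass(frozen=True)
class NormalizedBox:
    """Class index plus centre/size as fractions of the image dimensions.

    The box must lie fully inside the unit square: ``xc +- w/2`` and
    ``yc +- h/2`` stay within ``[0, 1]`` (to numerical tolerance).
    """

    cls: int
    xc: float
    yc: float
    w: float
    h: float

    def __post_init__(self) -> None:
        vals = (self.xc, self.yc, self.w, self.h)
        if not all(-_EPS <= v <= 1.0 + _EPS for v in vals):
            raise ValidationError(f"normalized coordinates outside [0, 1]: {vals}")
        if self.w <= 0.0 or self.h <= 0.0:
            raise ValidationError(f"normalized box with non-positive size: {vals}")
        if (
            self.xc - self.w / 2.0 < -_EPS
            or self.xc + self.w / 2.0 > 1.0 + _EPS
            or self.yc - self.h / 2.0 < -_EPS
            or self.yc + self.h / 2.0 > 1.0 + _EPS
        ):
            raise ValidationError(f"normalized box extends outside the unit square: {vals}")


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes, computed on continuous areas.

    Returns 0 for disjoint boxes and exactly 1 for identical ones.
    """
    inter = a.intersection_area(b)
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


def to_normalized(b: Box, image_w: int, image_h: int, cls: int = 0) -> NormalizedBox:
    """Convert a pixel box to fractional centre/size coordinates.

    The box must lie within the image bounds; round-trips with
    :func:`from_normalized` to within half a pixel per coordinate.
    """
    if image_w <= 0 or image_h <= 0:
        raise ValidationError(f"non-positive image dimensions ({image_w}, {image_h})")
    if b.x0 < -_EPS or b.y0 < -_EPS or b.x1 > image_w + _EPS or b.y1 > image_h + _EPS:
        raise ValidationError(
            f"box ({b.x0}, {b.y0}, {b.x1}, {b.y1}) exceeds image bounds "
            f"({image_w} x {image_h})"
        )
    return NormalizedBox(
        cls=cls,
        xc=(b.x0 + b.x1) / 2.0 / image_w,
        yc=(b.y0 + b.y1) / 2.0 / image_h,
        w=b.width / image_w,
        h=b.height / image_h,
    )


def from_normalized(nb: NormalizedBox, image_w: int, image_h: int) -> Box:
    """Convert fractional coordinates to an integer pixel box.

    ``x0``/``y0`` are rounded half-up; ``x1 = x0 + round(w * W)`` so the box
    width is stable under round trips.
    """
    if image_w <= 0 or image_h <= 0:
        raise ValidationError(f"non-positive image dimensions ({image_w}, {image_h})")
    w = _round_half_up(nb.w * image_w)
    h = _round_half_up(nb.h * image_h)
    x0 = _round_half_up(nb.xc * image_w - nb.w * image_w / 2.0)
    y0 = _round_half_up(nb.yc * image_h - nb.h * image_h / 2.0)
    return Box(x0, y0, x0 + max(w, 1), y0 + max(h, 1))
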