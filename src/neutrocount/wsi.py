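"""Calibrated high-powered-field tiling and overlapping sliding windows.

A slide scanner is calibrated in pixels per millimetre; the diagnostic
counting unit is the high-powered field (HPF), an area of about 0.2 mm²
matching what a pathologist sees through a 40x objective. The HPF grid is a
square, non-overlapping tiling with side ``sqrt(hpf_area) * px_per_mm``
(square tiles best approximate the circular optical field given that only
the area is specified). At the reference calibration of 4,050 px/mm this
gives 1,811-pixel tiles.

Detection on large images runs in overlapping sliding windows so that small
objects are seen whole by at least one window; duplicates in the overlap
zones are removed by non-maximum suppression when window results are merged
back into slide coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .detect import Detection
from .errors import ValidationError
from .geometry import Box, iou

REFERENCE_PX_PER_MM = 4050.0
REFERENCE_HPF_AREA_MM2 = 0.2


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of a scanned slide."""

    px_per_mm: float = REFERENCE_PX_PER_MM
    hpf_area: float = REFERENCE_HPF_AREA_MM2

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0 or self.hpf_area <= 0:
            raise ValidationError("px_per_mm and hpf_area must be positive")


@dataclass
class HpfGrid:
    """Non-overlapping square tiling of a slide into HPF-sized rectangles."""

    tiles: list[Box]
    tile_side: int
    slide_w: int
    slide_h: int

    @property
    def n_cols(self) -> int:
        return math.ceil(self.slide_w / self.tile_side)

    @property
    def n_rows(self) -> int:
        return math.ceil(self.slide_h / self.tile_side)

    def tile_index(self, x: float, y: float) -> int:
        """Raster-order index of the tile containing point (x, y).

        Points on a shared boundary belong to the tile to the right/below
        (half-open tiles); points at the slide's far edge clamp inward.
        """
        col = min(int(x // self.tile_side), self.n_cols - 1)
        row = min(int(y // self.tile_side), self.n_rows - 1)
        return row * self.n_cols + col


@dataclass
class WindowPlan:
    """Overlapping sliding windows covering a slide."""

    windows: list[Box]
    window_side: int
    overlap_fraction: float
    slide_w: int
    slide_h: int

    @property
    def stride(self) -> int:
        return max(1, int(self.window_side * (1.0 - self.overlap_fraction)))


def hpf_side(c: Calibration) -> int:
    """Side in pixels of a square tile with the calibrated HPF area."""
    return int(round(math.sqrt(c.hpf_area) * c.px_per_mm))


def make_hpf_grid(slide_w: int, slide_h: int, c: Calibration | None = None) -> HpfGrid:
    """Tile a slide into HPF-sized squares in raster order.

    Interior tiles are exactly ``side x side``; tiles at the right and
    bottom edges are truncated at the slide bounds, so tile areas sum to the
    slide area exactly.
    """
    if slide_w < 1 or slide_h < 1:
        raise ValidationError("slide dimensions must be >= 1 px")
    side = hpf_side(c or Calibration())
    tiles = [
        Box(x, y, min(x + side, slide_w), min(y + side, slide_h))
        for y in range(0, slide_h, side)
        for x in range(0, slide_w, side)
    ]
    return HpfGrid(tiles, side, slide_w, slide_h)


def filter_partial_tiles(grid: HpfGrid, min_fill: float = 0.5) -> list[int]:
    """Indices of grid tiles with at least ``min_fill`` of the full HPF area.

    Edge tiles truncated at the slide boundary cover less tissue area than
    one HPF; callers can use this to exclude them from per-case count
    distributions. Returns raster-order indices into ``grid.tiles``.
    """
    full = float(grid.tile_side) ** 2
    return [i for i, t in enumerate(grid.tiles) if t.area >= min_fill * full]


def _axis_offsets(dim: int, window: int, stride: int) -> list[int]:
    if dim <= window:
        return [0]
    offsets = [0]
    pos = stride
    last = dim - window
    while pos < last:
        offsets.append(pos)
        pos += stride
    offsets.append(last)
    return offsets


def plan_windows(
    slide_w: int,
    slide_h: int,
    window: int = 512,
    overlap: float = 0.3,
) -> WindowPlan:
    """Plan overlapping detection windows over a slide.

    Stride is ``floor(window * (1 - overlap))``; the final offset on each
    axis is clamped flush to the slide edge so coverage is complete, and all
    windows are full-size whenever the slide is at least one window wide.
    Slides smaller than the window get a single truncated window.
    """
    if window < 1:
        raise ValidationError("window side must be >= 1 px")
    if not 0.0 <= overlap < 1.0:
        raise ValidationError(f"overlap must lie in [0, 1), got {overlap}")
    if slide_w < 1 or slide_h < 1:
        raise ValidationError("slide dimensions must be >= 1 px")
    stride = max(1, int(math.floor(window * (1.0 - overlap))))
    xs = _axis_offsets(slide_w, window, stride)
    ys = _axis_offsets(slide_h, window, stride)
    windows = [
        Box(x, y, min(x + window, slide_w), min(y + window, slide_h))
        for y in ys
        for x in xs
    ]
    return WindowPlan(windows, window, overlap, slide_w, slide_h)


def nms(dets: Sequence[Detection], iou_thresh: float = 0.5) -> list[Detection]:
    """Greedy non-maximum suppression keeping the higher-confidence member."""
    ordered = sorted(dets, key=lambda d: (-d.confidence, d.box.x0, d.box.y0))
    kept: list[Detection] = []
    for d in ordered:
        if all(iou(d.box, k.box) < iou_thresh for k in kept):
            kept.append(d)
    return kept


def merge_window_detections(
    per_window: Mapping[Box, Sequence[Detection]],
    plan: WindowPlan,
    dedup_iou: float = 0.5,
) -> list[Detection]:
    """Translate per-window detections to slide coordinates and deduplicate.

    Each detection must lie within its window; duplicates arising from the
    window overlap (pairs with IOU >= ``dedup_iou``) are resolved by greedy
    NMS keeping the higher confidence. The result is sorted by descending
    confidence. Merging an already merged set changes nothing.
    """
    plan_windows_set = {
        (w.x0, w.y0, w.x1, w.y1) for w in plan.windows
    }
    translated: list[Detection] = []
    for win, dets in per_window.items():
        if (win.x0, win.y0, win.x1, win.y1) not in plan_windows_set:
            raise ValidationError(f"window {win} is not part of the plan")
        for d in dets:
            if (
                d.box.x0 < -1e-9
                or d.box.y0 < -1e-9
                or d.box.x1 > win.width + 1e-9
                or d.box.y1 > win.height + 1e-9
            ):
                raise ValidationError(
                    f"detection {d.box} outside its {win.width} x {win.height} window"
                )
            translated.append(Detection(d.box.translate(win.x0, win.y0), d.confidence))
    return nms(translated, dedup_iou)
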