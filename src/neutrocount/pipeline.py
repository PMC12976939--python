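"""End-to-end orchestration: sliced detection on slides, per-HPF counting,
and case diagnosis.

``detect_sliced`` is the driver that corresponds to running a detector
through an inference slicer: plan overlapping windows, detect per window,
drop candidates cut by an interior window border (the neighbouring window
sees them whole), and merge back to slide coordinates with cross-window
NMS.

``process_case`` runs a synthetic case bundle through the full chain —
window plan, detector, merge, confidence filter, per-HPF counting,
median-threshold classification — exactly as a scanned slide would be
processed.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np

from .detect import Detection, DetectorContract, ReferenceDetector, filter_by_confidence
from .diagnose import INFECTED, NOT_INFECTED, CaseRecord, summarize_case
from .errors import ValidationError
from .geometry import Box
from .synthgen import CaseBundle
from .wsi import HpfGrid, WindowPlan, merge_window_detections, plan_windows

DetectorLike = DetectorContract | Callable[[np.ndarray], list[Detection]]


def _call_detector(detector: DetectorLike, tile: np.ndarray) -> list[Detection]:
    if hasattr(detector, "detect"):
        return detector.detect(tile)  # type: ignore[union-attr]
    return detector(tile)  # type: ignore[operator]


def _drop_border_cut(
    dets: Sequence[Detection], win: Box, slide_w: int, slide_h: int, margin: float = 2.0
) -> list[Detection]:
    """Remove detections touching an interior window border.

    An object cut by a window edge is seen whole by an overlapping
    neighbour; keeping the cut fragment would create near-duplicates that
    NMS cannot always pair. Borders that coincide with the slide edge are
    kept.
    """
    kept = []
    for d in dets:
        cut = (
            (d.box.x0 <= margin and win.x0 > 0)
            or (d.box.y0 <= margin and win.y0 > 0)
            or (d.box.x1 >= win.width - margin and win.x1 < slide_w)
            or (d.box.y1 >= win.height - margin and win.y1 < slide_h)
        )
        if not cut:
            kept.append(d)
    return kept


def detect_sliced(
    slide: np.ndarray,
    detector: DetectorLike | None = None,
    window: int = 512,
    overlap: float = 0.3,
    dedup_iou: float = 0.5,
) -> tuple[list[Detection], WindowPlan]:
    """Run sliced inference over a slide raster.

    Returns merged detections in slide coordinates (descending confidence)
    plus the window plan used.
    """
    detector = detector or ReferenceDetector()
    h, w = slide.shape[:2]
    plan = plan_windows(w, h, window, overlap)
    per_window: dict[Box, list[Detection]] = {}
    for win in plan.windows:
        crop = slide[int(win.y0) : int(win.y1), int(win.x0) : int(win.x1)]
        dets = _call_detector(detector, crop)
        per_window[win] = _drop_border_cut(dets, win, w, h)
    merged = merge_window_detections(per_window, plan, dedup_iou)
    return merged, plan


def count_by_hpf(dets: Sequence[Detection], grid: HpfGrid) -> np.ndarray:
    """Count detections per HPF tile by box-centre containment.

    Each detection is assigned to exactly one tile — the one containing its
    box centre (boundary points go to the tile to the right/below), so no
    object is counted twice however it straddles tile borders.
    """
    counts = np.zeros(len(grid.tiles), dtype=np.int64)
    for d in dets:
        cx, cy = d.box.center
        if not (0 <= cx < grid.slide_w and 0 <= cy < grid.slide_h):
            raise ValidationError(f"detection centre ({cx}, {cy}) outside the slide")
        counts[grid.tile_index(cx, cy)] += 1
    return counts


def assemble_mosaic(
    tiles: Sequence[np.ndarray], n_cols: int | None = None
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Paste equally sized tiles into one slide raster, raster order.

    Returns the mosaic and the (x, y) offset of each tile — the plain-text
    stand-in for a pyramidal slide used throughout the tests.
    """
    if not tiles:
        raise ValidationError("assemble_mosaic needs at least one tile")
    th, tw = tiles[0].shape[:2]
    if any(t.shape[:2] != (th, tw) for t in tiles):
        raise ValidationError("all mosaic tiles must share one size")
    n = len(tiles)
    n_cols = n_cols or int(np.ceil(np.sqrt(n)))
    n_rows = int(np.ceil(n / n_cols))
    slide = np.zeros((n_rows * th, n_cols * tw, tiles[0].shape[2]), dtype=tiles[0].dtype)
    slide[..., :] = 255
    offsets = []
    for i, t in enumerate(tiles):
        r, c = divmod(i, n_cols)
        slide[r * th : (r + 1) * th, c * tw : (c + 1) * tw] = t
        offsets.append((c * tw, r * th))
    return slide, offsets


def process_case(
    bundle: CaseBundle,
    detector: DetectorLike | None = None,
    window: int = 512,
    overlap: float = 0.3,
    confidence_threshold: float = 0.5,
    iou_dedup: float = 0.5,
    diagnosis_threshold: float = 5.0,
    rule: str = "ge",
) -> CaseRecord:
    """Diagnose one synthetic case through the full detection pipeline.

    Each HPF tile image goes through the sliced-inference driver (a 224 px
    tile fits in a single 512 px window, but the same code path handles
    larger patches), the merged detections are confidence-filtered at the
    operating threshold, and the per-HPF counts are summarized and
    classified by the median rule.
    """
    detector = detector or ReferenceDetector()
    counts = []
    for tile in bundle.tiles:
        dets, _ = detect_sliced(tile, detector, window, overlap, iou_dedup)
        counts.append(len(filter_by_confidence(dets, confidence_threshold)))
    refs = {"truth": INFECTED if bundle.infected else NOT_INFECTED}
    record = summarize_case(
        bundle.case_id, counts, refs, diagnosis_threshold, rule
    )
    return record


def label_recovery(
    records: Sequence[CaseRecord], truths: Mapping[str, bool]
) -> float:
    """Fraction of cases whose predicted label matches the planted truth."""
    if not records:
        raise ValidationError("no case records")
    hits = sum(
        (r.predicted == INFECTED) == bool(truths[r.case_id]) for r in records
    )
    return hits / len(records)
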