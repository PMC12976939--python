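"""Detection-vs-ground-truth matching, metrics, and agreement statistics.

A detection is a true positive when it claims an unmatched ground-truth box
with IOU strictly greater than the matching threshold (default 0.5);
detections are processed in descending confidence and each truth box may be
claimed once (the standard greedy one-to-one assignment used in detection
benchmarks). Unclaimed detections are false positives; unclaimed truth
boxes are false negatives.

Precision = TP/(TP+FP) (positive predictive value), recall = TP/(TP+FN)
(sensitivity), and F1 is their harmonic mean. Degenerate denominators are
flagged as undefined rather than silently zeroed, so cohort aggregation
cannot be corrupted by empty images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .annot_io import AnnotationSet, _greedy_iou_pairs
from .detect import Detection, filter_by_confidence
from .errors import ValidationError
from .geometry import Box, iou


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed tables conventionally do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MatchResult:
    """Outcome of matching one detection set against one truth set."""

    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int, float]]  # (detection idx, truth idx, IOU)


@dataclass
class EvalMetrics:
    """Precision/recall/F1 with explicit undefined flags.

    A metric is undefined when its denominator is zero (no predicted
    positives for precision, no actual positives for recall, both for F1);
    undefined values are stored as ``nan`` with the matching flag False.
    """

    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True
    f1_defined: bool = True

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """Values rounded half-up for display against printed tables."""
        return (
            round_half_up(self.precision, ndigits) if self.precision_defined else math.nan,
            round_half_up(self.recall, ndigits) if self.recall_defined else math.nan,
            round_half_up(self.f1, ndigits) if self.f1_defined else math.nan,
        )

    def as_percents(self) -> tuple[float, float, float]:
        """Whole-percent rounding, the other display convention in reports."""
        return (
            round_half_up(100 * self.precision, 0) if self.precision_defined else math.nan,
            round_half_up(100 * self.recall, 0) if self.recall_defined else math.nan,
            round_half_up(100 * self.f1, 0) if self.f1_defined else math.nan,
        )


def match(
    dets: Sequence[Detection], truths: Sequence[Box], iou_thresh: float = 0.5
) -> MatchResult:
    """Greedy confidence-ordered one-to-one matching at IOU > ``iou_thresh``.

    "Greater than" is strict by default; pass a marginally smaller
    threshold to emulate a >= rule.
    """
    if not 0.0 < iou_thresh <= 1.0:
        raise ValidationError(f"iou_thresh must lie in (0, 1], got {iou_thresh}")
    order = sorted(
        range(len(dets)), key=lambda i: (-dets[i].confidence, i)
    )
    claimed: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for di in order:
        best_j, best_v = -1, iou_thresh
        for j, t in enumerate(truths):
            if j in claimed:
                continue
            v = iou(dets[di].box, t)
            if v > best_v:
                best_j, best_v = j, v
        if best_j >= 0:
            claimed.add(best_j)
            pairs.append((di, best_j, best_v))
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fp=len(dets) - tp,
        fn=len(truths) - tp,
        matched_pairs=sorted(pairs),
    )


def metrics(tp: int, fp: int, fn: int) -> EvalMetrics:
    """Precision, recall, and F1 from raw counts."""
    if min(tp, fp, fn) < 0:
        raise ValidationError("counts must be non-negative")
    p_def, r_def = tp + fp > 0, tp + fn > 0
    p = tp / (tp + fp) if p_def else math.nan
    r = tp / (tp + fn) if r_def else math.nan
    f_def = p_def and r_def
    # harmonic mean tends to 0 as both rates do, so 0/0 resolves to 0
    f = (2 * p * r / (p + r) if p + r > 0 else 0.0) if f_def else math.nan
    return EvalMetrics(p, r, f, p_def, r_def, f_def)


def evaluate(
    dets: Sequence[Detection], truths: Sequence[Box], iou_thresh: float = 0.5
) -> EvalMetrics:
    """Convenience: match then compute metrics."""
    m = match(dets, truths, iou_thresh)
    return metrics(m.tp, m.fp, m.fn)


def confidence_precision_curve(
    dets: Sequence[Detection],
    truths: Sequence[Box],
    thresholds: Sequence[float],
    iou_thresh: float = 0.5,
) -> list[tuple[float, float]]:
    """Precision after confidence filtering, per threshold.

    The curve that motivates an operating point for the confidence cut-off:
    sweeping the threshold up trades recall for precision.
    """
    out: list[tuple[float, float]] = []
    for t in thresholds:
        kept = filter_by_confidence(dets, t)
        m = match(kept, truths, iou_thresh)
        em = metrics(m.tp, m.fp, m.fn)
        out.append((t, em.precision))
    return out


def interobserver(
    a: AnnotationSet, b: AnnotationSet, iou_thresh: float = 0.5
) -> EvalMetrics:
    """Agreement metrics between two annotators of the same image.

    ``b`` is treated as ground truth and ``a`` as predictions at uniform
    confidence; since confidences cannot break ties, pairs are matched
    greedily by descending IOU (strictly above the threshold).
    """
    if (a.image_w, a.image_h) != (b.image_w, b.image_h):
        raise ValidationError(
            f"image dimensions differ: {a.image_w} x {a.image_h} vs "
            f"{b.image_w} x {b.image_h}"
        )
    boxes_a = a.pixel_boxes()
    boxes_b = b.pixel_boxes()
    pairs = _greedy_iou_pairs(boxes_a, boxes_b, iou_thresh, strict=True)
    tp = len(pairs)
    return metrics(tp, len(boxes_a) - tp, len(boxes_b) - tp)
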