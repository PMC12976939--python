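"""Reading, writing, rescaling, and merging of bounding-box annotations.

Label files follow the normalized one-text-file-per-image detection
convention: one object per line, ``cls xc yc w h``, all coordinates as
fractions of the image dimensions. A single object class (0 = neutrophil)
is used throughout, but the class index is preserved verbatim.

``consensus_merge`` pairs two annotators' boxes by IOU and splits the result
into an agreed set and two disputed sets; disputed boxes are intended for
human adjudication, mirroring how double-annotated histology ground truth is
resolved in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ParseError, ValidationError
from .geometry import Box, NormalizedBox, from_normalized, iou


@dataclass
class AnnotationSet:
    """All annotated boxes of one image, in normalized coordinates."""

    image_id: str
    image_w: int
    image_h: int
    boxes: list[NormalizedBox] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.boxes)

    def pixel_boxes(self) -> list[Box]:
        """Boxes converted to pixel coordinates of this image."""
        return [from_normalized(nb, self.image_w, self.image_h) for nb in self.boxes]


@dataclass
class ConsensusReport:
    """Outcome of merging two annotators' box sets for one image.

    Every input box lands in exactly one bucket: matched pairs contribute one
    averaged box to ``agreed``; unmatched boxes go to the respective disputed
    list for external review.
    """

    agreed: list[Box]
    disputed_a_only: list[Box]
    disputed_b_only: list[Box]


def read_labels(
    path: str | Path, image_w: int, image_h: int, image_id: str | None = None
) -> AnnotationSet:
    """Parse a normalized label file into an :class:`AnnotationSet`.

    Each non-blank line must contain exactly five whitespace-separated
    numeric fields (integer class then four fractional coordinates). An
    empty file yields an empty set.
    """
    path = Path(path)
    boxes: list[NormalizedBox] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 5 fields, got {len(fields)}"
                )
            try:
                cls = int(fields[0])
                xc, yc, w, h = (float(v) for v in fields[1:])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            try:
                boxes.append(NormalizedBox(cls, xc, yc, w, h))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return AnnotationSet(image_id or path.stem, image_w, image_h, boxes)


def write_labels(annots: AnnotationSet, path: str | Path) -> Path:
    """Write the set back out, 6-decimal fixed formatting per coordinate."""
    path = Path(path)
    with open(path, "w") as fh:
        for nb in annots.boxes:
            fh.write(f"{nb.cls} {nb.xc:.6f} {nb.yc:.6f} {nb.w:.6f} {nb.h:.6f}\n")
    return path


def rescale(
    image: np.ndarray, labels: AnnotationSet, factor: float
) -> tuple[np.ndarray, AnnotationSet]:
    """Resize an image/label pair by ``factor``.

    Normalized labels are invariant under uniform rescaling, so only the
    stored image dimensions change; pixel-space boxes scale with the image.
    Used to bring imagery to a common object scale (e.g. shrinking blood-film
    photographs until a neutrophil occupies roughly 40 x 40 px, the size it
    has in scanned histology sections).
    """
    if factor <= 0:
        raise ValidationError(f"rescale factor must be positive, got {factor}")
    h, w = image.shape[:2]
    new_w = int(round(w * factor))
    new_h = int(round(h * factor))
    if new_w < 2 or new_h < 2:
        raise ValidationError(
            f"rescale factor {factor} collapses {w} x {h} to {new_w} x {new_h}"
        )
    if factor == 1.0:
        out = image.copy()
    else:
        out = np.asarray(
            Image.fromarray(image).resize((new_w, new_h), Image.Resampling.BILINEAR)
        )
    return out, AnnotationSet(labels.image_id, new_w, new_h, list(labels.boxes))


def scale_to_height(image_h: int, target_h: int) -> float:
    """Factor that maps an image of height ``image_h`` to ``target_h`` pixels."""
    if image_h <= 0 or target_h <= 0:
        raise ValidationError("heights must be positive")
    return target_h / image_h


def _greedy_iou_pairs(
    a: list[Box], b: list[Box], iou_thresh: float, strict: bool
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one pairing by descending IOU above a threshold."""
    cands = []
    for i, ba in enumerate(a):
        for j, bb in enumerate(b):
            v = iou(ba, bb)
            if (v > iou_thresh) if strict else (v >= iou_thresh):
                cands.append((v, i, j))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for v, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, v))
    return pairs


def consensus_merge(
    a: AnnotationSet, b: AnnotationSet, iou_thresh: float = 0.5
) -> ConsensusReport:
    """Merge two annotators' sets into agreed and disputed boxes.

    Pairs with IOU >= ``iou_thresh`` are matched greedily in descending IOU,
    each box used at most once; an agreed box is the coordinate-wise mean of
    its pair. Everything unmatched is routed to the annotator's disputed
    list. Box conservation holds: ``2 * |agreed| + |disputed_a| +
    |disputed_b| == |a| + |b|``.
    """
    if (a.image_w, a.image_h) != (b.image_w, b.image_h):
        raise ValidationError(
            f"image dimensions differ: {a.image_w} x {a.image_h} vs "
            f"{b.image_w} x {b.image_h}"
        )
    boxes_a = a.pixel_boxes()
    boxes_b = b.pixel_boxes()
    pairs = _greedy_iou_pairs(boxes_a, boxes_b, iou_thresh, strict=False)
    agreed = [
        Box(
            (boxes_a[i].x0 + boxes_b[j].x0) / 2.0,
            (boxes_a[i].y0 + boxes_b[j].y0) / 2.0,
            (boxes_a[i].x1 + boxes_b[j].x1) / 2.0,
            (boxes_a[i].y1 + boxes_b[j].y1) / 2.0,
        )
        for i, j, _ in pairs
    ]
    matched_a = {i for i, _, _ in pairs}
    matched_b = {j for _, j, _ in pairs}
    return ConsensusReport(
        agreed=agreed,
        disputed_a_only=[bx for i, bx in enumerate(boxes_a) if i not in matched_a],
        disputed_b_only=[bx for j, bx in enumerate(boxes_b) if j not in matched_b],
    )


def apply_exclusions(boxes: list[Box], excluded: list[Box]) -> list[Box]:
    """Drop boxes equal to an entry of an explicit exclusion list.

    Models post-consensus removal of uncertain ground-truth objects by an
    expert reviewer; exclusion is by exact coordinates, not by judgement.
    """
    excl = {(e.x0, e.y0, e.x1, e.y1) for e in excluded}
    return [b for b in boxes if (b.x0, b.y0, b.x1, b.y1) not in excl]
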