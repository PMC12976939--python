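"""Detector contract, confidence filtering, and the rule-based reference detector.

Any detector — including an external trained network — plugs into the
pipeline by satisfying :class:`DetectorContract`: a pure function from a
colour tile to a list of :class:`Detection` with boxes inside the tile.
The package ships a deterministic rule-based reference detector built on
the morphological definition of a neutrophil (a cluster of 2-5 separate
dark nuclear lobes within a lighter cytoplasm), which solves the synthetic
fixtures without trained weights and exercises every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage

from ._kernels import dark_mask, ring_light_fraction
from .errors import ValidationError
from .geometry import Box

#: luminance below which a pixel is treated as nuclear material
_DARK_LUMINANCE = 120.0
#: luminance above which a pixel counts as light cytoplasm/background
_LIGHT_LUMINANCE = 160.0
#: minimum component area, as a fraction of scale^2, to count as a lobe
_MIN_LOBE_AREA_FRAC = 0.025
_SCORE_WEIGHTS = (0.6, 0.25, 0.15)  # lobe count, nuclear area, cytoplasm annulus


@dataclass(frozen=True)
class Detection:
    """One detected object: a pixel box plus a confidence in [0, 1]."""

    box: Box
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(f"confidence outside [0, 1]: {self.confidence}")


@runtime_checkable
class DetectorContract(Protocol):
    """What the pipeline requires of a detector."""

    #: side of the tiles the detector expects, in pixels
    input_size: int
    #: linear size of the target object the detector was built for, pixels
    target_scale: int

    def detect(self, tile: np.ndarray) -> list[Detection]:
        """Return detections with boxes inside the tile; pure in the input."""
        ...


def filter_by_confidence(
    dets: Sequence[Detection], threshold: float = 0.5
) -> list[Detection]:
    """Keep detections with confidence >= ``threshold``, preserving order."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold outside [0, 1]: {threshold}")
    return [d for d in dets if d.confidence >= threshold]


def _lobe_score(k: int) -> float:
    if 2 <= k <= 5:
        return 1.0
    if k in (6, 7):
        return 0.3
    return 0.0


def _area_score(area: float, scale: float) -> float:
    """Trapezoid on total nuclear area relative to the (scale/2)^2 pi cell disc."""
    ratio = area / (np.pi * (scale / 2.0) ** 2)
    if ratio < 0.03:
        return 0.0
    if ratio < 0.08:
        return (ratio - 0.03) / 0.05
    if ratio <= 0.8:
        return 1.0
    if ratio <= 1.2:
        return (1.2 - ratio) / 0.4
    return 0.0


_RING_ANGLES = np.linspace(0.0, 2 * np.pi, 24, endpoint=False)
#: unit offsets of the two sampled rings, relative to scale
_RING_UNIT = np.concatenate(
    [
        r * np.stack([np.cos(_RING_ANGLES), np.sin(_RING_ANGLES)], axis=1)
        for r in (0.48, 0.58)
    ]
)


def _annulus_score(tile: np.ndarray, cx: float, cy: float, scale: float) -> float:
    """Fraction of sampled ring pixels around the candidate that are light."""
    return ring_light_fraction(tile, _RING_UNIT * scale, cx, cy, _LIGHT_LUMINANCE)


def _single_linkage_groups(centroids: np.ndarray, link_dist: float) -> list[list[int]]:
    """Union components whose centroids lie within ``link_dist``."""
    n = len(centroids)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    diff = centroids[:, None, :] - centroids[None, :, :]
    close = (diff**2).sum(axis=2) <= link_dist * link_dist
    for i, j in zip(*np.nonzero(np.triu(close, k=1))):
        pi, pj = find(int(i)), find(int(j))
        if pi != pj:
            parent[pi] = pj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def reference_detect(tile: np.ndarray, scale: int = 40) -> list[Detection]:
    """Detect neutrophil-like cells in a colour tile by morphological rules.

    Pipeline: threshold dark nuclear material on luminance, take connected
    components above a minimum lobe area, group components whose centroids
    fall within ``scale / 2`` of each other (single linkage) into candidate
    cells, then score each candidate by lobe count (2-5 favoured), total
    nuclear area relative to the cell disc, and the presence of a lighter
    surrounding annulus. The weighted score, clipped to [0, 1], is the
    confidence; the emitted box is the grouped-lobe bounding box padded to
    at least ``0.9 * scale`` per side. Deterministic in the input.
    """
    if tile.ndim != 3 or tile.shape[2] < 3:
        raise ValidationError("reference_detect requires an H x W x 3 colour raster")
    dark = dark_mask(np.ascontiguousarray(tile[..., :3]), _DARK_LUMINANCE)
    if not dark.any():
        return []
    lbl, n_comp = ndimage.label(dark)
    ys, xs = np.nonzero(dark)
    labs = lbl[ys, xs]
    areas = np.bincount(labs, minlength=n_comp + 1)[1:]
    keep = np.flatnonzero(areas >= _MIN_LOBE_AREA_FRAC * scale * scale) + 1
    if keep.size == 0:
        return []
    sum_x = np.bincount(labs, weights=xs, minlength=n_comp + 1)[1:]
    sum_y = np.bincount(labs, weights=ys, minlength=n_comp + 1)[1:]
    centroids = np.stack(
        [sum_x[keep - 1] / areas[keep - 1], sum_y[keep - 1] / areas[keep - 1]], axis=1
    )
    slices = ndimage.find_objects(lbl)

    detections: list[Detection] = []
    h, w = dark.shape
    for group in _single_linkage_groups(centroids, scale / 2.0):
        comp_ids = [keep[g] for g in group]
        k = len(comp_ids)
        total_area = float(areas[[c - 1 for c in comp_ids]].sum())
        x0 = min(slices[c - 1][1].start for c in comp_ids)
        x1 = max(slices[c - 1][1].stop for c in comp_ids)
        y0 = min(slices[c - 1][0].start for c in comp_ids)
        y1 = max(slices[c - 1][0].stop for c in comp_ids)
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0

        wl, wa, wn = _SCORE_WEIGHTS
        conf = (
            wl * _lobe_score(k)
            + wa * _area_score(total_area, scale)
            + wn * _annulus_score(tile, cx, cy, scale)
        )
        conf = float(np.clip(conf, 0.0, 1.0))

        side = 0.9 * scale
        bw, bh = max(float(x1 - x0), side), max(float(y1 - y0), side)
        bx0 = max(cx - bw / 2.0, 0.0)
        by0 = max(cy - bh / 2.0, 0.0)
        bx1 = min(cx + bw / 2.0, float(w))
        by1 = min(cy + bh / 2.0, float(h))
        if bx1 - bx0 < 2 or by1 - by0 < 2:
            continue
        detections.append(Detection(Box(bx0, by0, bx1, by1), conf))

    detections.sort(key=lambda d: (-d.confidence, d.box.x0, d.box.y0))
    return detections


@dataclass
class ReferenceDetector:
    """Bundles :func:`reference_detect` behind :class:`DetectorContract`."""

    input_size: int = 224
    target_scale: int = 40

    def detect(self, tile: np.ndarray) -> list[Detection]:
        return reference_detect(tile, scale=self.target_scale)


def detections_to_label_lines(
    dets: Sequence[Detection], image_w: int, image_h: int
) -> list[str]:
    """Normalized label lines with the confidence appended as a sixth field."""
    from .geometry import to_normalized

    lines = []
    for d in dets:
        nb = to_normalized(d.box, image_w, image_h)
        lines.append(
            f"{nb.cls} {nb.xc:.6f} {nb.yc:.6f} {nb.w:.6f} {nb.h:.6f} "
            f"{d.confidence:.4f}"
        )
    return lines


def detections_to_csv_rows(
    image_id: str, dets: Sequence[Detection]
) -> list[dict[str, object]]:
    """Rows for the detection CSV dialect (image_id, x0, y0, x1, y1, confidence)."""
    return [
        {
            "image_id": image_id,
            "x0": d.box.x0,
            "y0": d.box.y0,
            "x1": d.box.x1,
            "y1": d.box.y1,
            "confidence": d.confidence,
        }
        for d in dets
    ]
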