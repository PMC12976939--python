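"""Compiled inner loops (numba) for tile rendering and nuclear thresholding.

All randomness stays outside these kernels: callers pre-draw disc positions
and colours with a seeded numpy generator, so outputs remain pure functions
of the parameters while the pixel loops run at native speed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def render_tile(
    h: int,
    w: int,
    tint: np.ndarray,
    discs: np.ndarray,
    noise: np.ndarray,
) -> np.ndarray:
    """Render a full tile: background tint, discs in order, per-pixel
    luminance noise (pre-drawn by the caller), clipped uint8 output."""
    img = np.empty((h, w, 3), np.float32)
    for y in range(h):
        for x in range(w):
            img[y, x, 0] = tint[0]
            img[y, x, 1] = tint[1]
            img[y, x, 2] = tint[2]
    paint_discs(img, discs)
    out = np.empty((h, w, 3), np.uint8)
    for y in range(h):
        for x in range(w):
            n = noise[y, x]
            for c in range(3):
                v = img[y, x, c] + n
                if v < 0.0:
                    v = 0.0
                elif v > 255.0:
                    v = 255.0
                out[y, x, c] = np.uint8(v)
    return out


@njit(cache=True)
def paint_discs(img: np.ndarray, discs: np.ndarray) -> None:
    """Paint filled discs into a float32 H x W x 3 image, in order.

    ``discs`` rows are (cx, cy, r, red, green, blue); later rows overwrite
    earlier ones where they overlap.
    """
    h, w = img.shape[:2]
    for i in range(discs.shape[0]):
        cx, cy, r = discs[i, 0], discs[i, 1], discs[i, 2]
        r2 = r * r
        x0 = max(int(cx - r) - 1, 0)
        x1 = min(int(cx + r) + 2, w)
        y0 = max(int(cy - r) - 1, 0)
        y1 = min(int(cy + r) + 2, h)
        for y in range(y0, y1):
            dy2 = (y - cy) * (y - cy)
            for x in range(x0, x1):
                if (x - cx) * (x - cx) + dy2 <= r2:
                    img[y, x, 0] = discs[i, 3]
                    img[y, x, 1] = discs[i, 4]
                    img[y, x, 2] = discs[i, 5]


@njit(cache=True)
def place_greedy(
    cand: np.ndarray,
    existing: np.ndarray,
    mutual_d2: float,
    existing_d2: float,
) -> tuple[np.ndarray, int]:
    """Greedy rejection placement from pre-drawn candidates.

    For each of the ``n`` objects, scan its candidate row and keep the
    first point at squared distance >= ``mutual_d2`` from previously placed
    points and >= ``existing_d2`` from ``existing``. Returns the placed
    points and how many were placed (== n on success).
    """
    n, tries = cand.shape[0], cand.shape[1]
    out = np.empty((n, 2), np.float64)
    placed = 0
    for i in range(n):
        found = False
        for t in range(tries):
            x, y = cand[i, t, 0], cand[i, t, 1]
            ok = True
            for j in range(existing.shape[0]):
                dx = x - existing[j, 0]
                dy = y - existing[j, 1]
                if dx * dx + dy * dy < existing_d2:
                    ok = False
                    break
            if ok and mutual_d2 > 0.0:
                for j in range(placed):
                    dx = x - out[j, 0]
                    dy = y - out[j, 1]
                    if dx * dx + dy * dy < mutual_d2:
                        ok = False
                        break
            if ok:
                out[placed, 0] = x
                out[placed, 1] = y
                placed += 1
                found = True
                break
        if not found:
            return out, placed
    return out, placed


@njit(cache=True)
def ring_light_fraction(
    tile: np.ndarray, ring: np.ndarray, cx: float, cy: float, light_thresh: float
) -> float:
    """Fraction of ring sample points whose luminance exceeds the threshold."""
    h, w = tile.shape[:2]
    light = 0
    for i in range(ring.shape[0]):
        x = int(cx + ring[i, 0])
        y = int(cy + ring[i, 1])
        if x < 0:
            x = 0
        elif x >= w:
            x = w - 1
        if y < 0:
            y = 0
        elif y >= h:
            y = h - 1
        lum = (
            0.299 * tile[y, x, 0] + 0.587 * tile[y, x, 1] + 0.114 * tile[y, x, 2]
        )
        if lum > light_thresh:
            light += 1
    return light / ring.shape[0]


@njit(cache=True)
def dark_mask(tile: np.ndarray, thresh: float) -> np.ndarray:
    """Boolean mask of pixels whose Rec.601 luminance is below ``thresh``."""
    h, w = tile.shape[:2]
    out = np.empty((h, w), np.bool_)
    for y in range(h):
        for x in range(w):
            lum = (
                0.299 * tile[y, x, 0]
                + 0.587 * tile[y, x, 1]
                + 0.114 * tile[y, x, 2]
            )
            out[y, x] = lum < thresh
    return out
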