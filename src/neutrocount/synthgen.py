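"""Seeded synthetic H&E-like fixtures: tiles, per-case HPF mosaics, splits.

The generator emulates the appearance cues that identify a neutrophil in an
H&E-stained section — a dark purple *lobulated* nucleus (2-5 separate lobes)
inside a lighter cytoplasm disc — among unlabelled distractors:

* ``lymphocyte``: one large round dark nucleus (single blob, no lobes);
* ``rbc``: an anucleate pink disc, never dark;
* ``necrotic_fragment``: a small irregular dark speck.

Tiles default to 224 x 224 px with ~40 x 40 px targets. Per-case fixtures
draw the per-HPF target count from a negative binomial, reflecting the
over-dispersed, "hot spot" clustering of neutrophil infiltrates in tissue;
infected and sterile cases differ only in the mean of that distribution
(defaults 8 vs 2, straddling the diagnostic threshold of 5 per HPF).

Every output is a pure function of its parameters including the seed;
per-HPF sub-seeds are derived with :class:`numpy.random.SeedSequence` so
tiles are reproducible individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import place_greedy, render_tile
from .annot_io import AnnotationSet
from .errors import CapacityError, ValidationError
from .geometry import Box, to_normalized

# Palette (RGB, uint8). Nuclear material is dark and blue-purple; everything
# else stays light enough that a luminance threshold separates the two.
BACKGROUND = (246, 226, 238)
CYTOPLASM = (236, 190, 205)
NUCLEUS = (94, 52, 122)
RBC = (232, 128, 138)
RBC_PALE_CENTER = (243, 178, 182)
NECROTIC = (70, 50, 72)

#: relative sizes of rendered structures, as fractions of ``target_size``
_LOBE_RADIUS = 0.15
_LYMPHOCYTE_RADIUS = 0.28
_RBC_RADIUS = 0.18
_EDGE_MARGIN = 0.65  # min distance of a target centre from the tile edge
#: ladder of minimum centre separations between nucleated objects; the first
#: rung guarantees the detector's lobe grouping never chains two cells, the
#: later rungs let crowded tiles render at the cost of possible undercounting
_SEPARATION_LADDER = (1.10, 0.95, 0.82, 0.70)


@dataclass
class TileParams:
    """Parameters of a single synthetic tile."""

    tile_w: int = 224
    tile_h: int = 224
    target_count: int = 8
    target_size: int = 40
    distractor_counts: dict[str, int] = field(
        default_factory=lambda: {"lymphocyte": 2, "rbc": 6, "necrotic_fragment": 2}
    )
    background_tint: tuple[int, int, int] = BACKGROUND
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_count < 0 or any(v < 0 for v in self.distractor_counts.values()):
            raise ValidationError("object counts must be non-negative")
        if self.target_size < 8:
            raise ValidationError(f"target_size must be >= 8 px, got {self.target_size}")
        unknown = set(self.distractor_counts) - {"lymphocyte", "rbc", "necrotic_fragment"}
        if unknown:
            raise ValidationError(f"unknown distractor kinds: {sorted(unknown)}")


@dataclass
class CaseParams:
    """Parameters of a synthetic per-case HPF series."""

    case_id: str
    infected: bool
    n_hpf: int = 200
    count_dispersion: float = 3.0
    mean_count_infected: float = 8.0
    mean_count_sterile: float = 2.0
    max_count: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hpf < 1:
            raise ValidationError("n_hpf must be >= 1")
        if self.count_dispersion <= 0:
            raise ValidationError("count_dispersion must be positive")
        if not self.mean_count_infected > self.mean_count_sterile:
            raise ValidationError(
                "mean_count_infected must exceed mean_count_sterile"
            )


@dataclass
class SplitSpec:
    """Train/validation/test fractions; must sum to 1."""

    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValidationError(f"fractions outside [0, 1]: {self.fractions}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError(f"fractions must sum to 1, got {sum(self.fractions)}")


@dataclass
class CaseBundle:
    """One synthetic case: tiles, labels, and the planted truth."""

    case_id: str
    infected: bool
    true_counts: np.ndarray  # planted target count per HPF tile
    tiles: list[np.ndarray]
    labels: list[AnnotationSet]
    params: CaseParams


def _jitter_color(
    rng: np.random.Generator, base: tuple[int, int, int], spread: int = 8
) -> tuple[int, int, int]:
    dr, dg, db = (int(v) for v in rng.integers(-spread, spread + 1, 3))
    return (
        min(max(base[0] + dr, 0), 255),
        min(max(base[1] + dg, 0), 255),
        min(max(base[2] + db, 0), 255),
    )


def _disc(cx: float, cy: float, r: float, color) -> tuple:
    """One row of the disc-spec array consumed by the paint kernel."""
    return (cx, cy, r, color[0], color[1], color[2])


def _place_centers(
    rng: np.random.Generator,
    n: int,
    w: int,
    h: int,
    margin: float,
    min_dist: float,
    existing: list[tuple[float, float]],
    tries_per_object: int = 300,
) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` centres at pairwise distance >= ``min_dist``."""
    if n == 0:
        return []
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise CapacityError(f"tile {w} x {h} too small for margin {margin}")
    cand = rng.uniform(
        (margin, margin), (w - margin, h - margin), size=(n, tries_per_object, 2)
    )
    exist = np.asarray(existing, dtype=np.float64).reshape(-1, 2)
    md2 = min_dist * min_dist
    pts, placed = place_greedy(cand, exist, md2, md2)
    if placed < n:
        raise CapacityError(
            f"could not place {n} objects at separation {min_dist:.0f} px "
            f"in a {w} x {h} tile"
        )
    return [(float(x), float(y)) for x, y in pts]


def _place_nucleated(
    rng: np.random.Generator, n_targets: int, n_other: int, p: TileParams
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Place nucleated objects, relaxing separation if the tile is crowded.

    Targets keep a wide edge margin so their ground-truth boxes stay inside
    the tile; nucleated distractors only need their own radius clear of the
    edge, which leaves them more room on crowded tiles.
    """
    last_err: CapacityError | None = None
    for frac in _SEPARATION_LADDER:
        state = rng.bit_generator.state
        try:
            targets = _place_centers(
                rng, n_targets, p.tile_w, p.tile_h,
                _EDGE_MARGIN * p.target_size, frac * p.target_size, [],
            )
            others = _place_centers(
                rng, n_other, p.tile_w, p.tile_h,
                0.3 * p.target_size, frac * p.target_size, targets,
            )
            return targets, others
        except CapacityError as exc:
            last_err = exc
            rng.bit_generator.state = state
    raise last_err  # type: ignore[misc]


def _neutrophil_discs(
    rng: np.random.Generator, cx: float, cy: float, size: int
) -> list[tuple]:
    """Lighter cytoplasm disc containing 2-5 separate dark lobes."""
    discs = [_disc(cx, cy, 0.5 * size, CYTOPLASM)]
    k = int(rng.integers(2, 6))
    r_l = _LOBE_RADIUS * size
    # ring radius large enough that lobes stay disjoint for this k
    d = max(0.19 * size, (2 * r_l + 2.0) / (2.0 * np.sin(np.pi / k)))
    start = rng.uniform(0, 2 * np.pi)
    color = _jitter_color(rng, NUCLEUS)
    for i in range(k):
        ang = start + 2 * np.pi * i / k + rng.uniform(-0.05, 0.05)
        rr = d + rng.uniform(-0.5, 0.5)
        discs.append(
            _disc(
                cx + rr * np.cos(ang),
                cy + rr * np.sin(ang),
                r_l + rng.uniform(-0.4, 0.4),
                color,
            )
        )
    return discs


def _lymphocyte_discs(
    rng: np.random.Generator, cx: float, cy: float, size: int
) -> list[tuple]:
    return [
        _disc(cx, cy, 0.36 * size, CYTOPLASM),
        _disc(cx, cy, _LYMPHOCYTE_RADIUS * size, _jitter_color(rng, NUCLEUS)),
    ]


def _rbc_discs(
    rng: np.random.Generator, cx: float, cy: float, size: int
) -> list[tuple]:
    r = _RBC_RADIUS * size * rng.uniform(0.85, 1.15)
    return [_disc(cx, cy, r, RBC), _disc(cx, cy, 0.45 * r, RBC_PALE_CENTER)]


def _necrotic_discs(
    rng: np.random.Generator, cx: float, cy: float, size: int
) -> list[tuple]:
    return [
        _disc(
            cx + rng.uniform(-2.5, 2.5),
            cy + rng.uniform(-2.5, 2.5),
            rng.uniform(1.2, 2.0),
            NECROTIC,
        )
        for _ in range(int(rng.integers(2, 4)))
    ]


def generate_tile(p: TileParams) -> tuple[np.ndarray, AnnotationSet]:
    """Render one tile and its ground-truth annotation set.

    Exactly ``target_count`` neutrophils are planted, each with a tight
    ground-truth box of ``target_size`` centred on the cell; distractors are
    rendered without labels. Identical parameters (including seed) give
    byte-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))

    n_lymph = p.distractor_counts.get("lymphocyte", 0)
    n_rbc = p.distractor_counts.get("rbc", 0)
    n_necro = p.distractor_counts.get("necrotic_fragment", 0)

    targets, others = _place_nucleated(rng, p.target_count, n_lymph + n_necro, p)
    lymphs = others[:n_lymph]
    necros = others[n_lymph:]
    # red cells are anucleate: only keep them off target cytoplasm
    rbcs = _place_rbcs(rng, n_rbc, p, targets)

    discs: list[tuple] = []
    for cx, cy in rbcs:
        discs += _rbc_discs(rng, cx, cy, p.target_size)
    for cx, cy in targets:
        discs += _neutrophil_discs(rng, cx, cy, p.target_size)
    for cx, cy in lymphs:
        discs += _lymphocyte_discs(rng, cx, cy, p.target_size)
    for cx, cy in necros:
        discs += _necrotic_discs(rng, cx, cy, p.target_size)
    if p.noise_sd > 0:
        noise = p.noise_sd * rng.standard_normal(
            size=(p.tile_h, p.tile_w), dtype=np.float32
        )
    else:
        noise = np.zeros((p.tile_h, p.tile_w), dtype=np.float32)
    tile = render_tile(
        p.tile_h,
        p.tile_w,
        np.asarray(p.background_tint, dtype=np.float32),
        np.asarray(discs, dtype=np.float32).reshape(-1, 6),
        noise,
    )

    half = p.target_size / 2.0
    boxes = [
        to_normalized(
            Box(cx - half, cy - half, cx + half, cy + half), p.tile_w, p.tile_h, cls=0
        )
        for cx, cy in targets
    ]
    annots = AnnotationSet(f"tile_{p.seed}", p.tile_w, p.tile_h, boxes)
    return tile, annots


def _place_rbcs(
    rng: np.random.Generator, n: int, p: TileParams, targets: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Red cells may crowd freely but stay off target cytoplasm discs."""
    if n == 0:
        return []
    keep_out2 = (0.62 * p.target_size) ** 2
    margin = _RBC_RADIUS * p.target_size
    cand = rng.uniform(
        (margin, margin),
        (p.tile_w - margin, p.tile_h - margin),
        size=(n, 200, 2),
    )
    tgt = np.asarray(targets, dtype=np.float64).reshape(-1, 2)
    pts, placed = place_greedy(cand, tgt, 0.0, keep_out2)
    if placed < n:
        raise CapacityError("could not place red-cell distractors")
    return [(float(x), float(y)) for x, y in pts]


def sample_hpf_counts(
    rng: np.random.Generator,
    n_hpf: int,
    mean: float,
    dispersion: float,
    max_count: int | None = None,
) -> np.ndarray:
    """Draw per-HPF counts from a negative binomial with given mean.

    Parameterized by mean ``m`` and dispersion ``theta`` (variance
    ``m + m^2 / theta``); small ``theta`` gives strongly clustered counts,
    large ``theta`` approaches Poisson. ``max_count`` truncates the upper
    tail so every tile remains renderable.
    """
    if mean < 0 or dispersion <= 0:
        raise ValidationError("mean must be >= 0 and dispersion positive")
    if mean == 0:
        return np.zeros(n_hpf, dtype=np.int64)
    counts = rng.negative_binomial(dispersion, dispersion / (dispersion + mean), n_hpf)
    if max_count is not None:
        counts = np.minimum(counts, max_count)
    return counts.astype(np.int64)


def generate_case(p: CaseParams) -> CaseBundle:
    """Render the ``n_hpf`` tiles of one case with known infection status.

    Per-HPF target counts come from the negative binomial above with mean
    ``mean_count_infected`` or ``mean_count_sterile``; distractor counts are
    Poisson around the tile defaults. Each tile uses a sub-seed derived from
    the case seed and HPF index, so any tile can be regenerated on its own.
    """
    root = np.random.SeedSequence(p.seed)
    case_rng = np.random.default_rng(root.spawn(1)[0])
    mean = p.mean_count_infected if p.infected else p.mean_count_sterile
    counts = sample_hpf_counts(case_rng, p.n_hpf, mean, p.count_dispersion, p.max_count)

    tiles: list[np.ndarray] = []
    labels: list[AnnotationSet] = []
    tile_seeds = root.spawn(p.n_hpf + 1)[1:]
    for i, (c, ss) in enumerate(zip(counts, tile_seeds)):
        tile_rng = np.random.default_rng(ss)
        distractors = {
            "lymphocyte": int(tile_rng.poisson(2.0)),
            "rbc": int(tile_rng.poisson(5.0)),
            "necrotic_fragment": int(tile_rng.poisson(1.5)),
        }
        tp = TileParams(
            target_count=int(c),
            distractor_counts=distractors,
            seed=int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF),
        )
        tile, annot = generate_tile(tp)
        annot.image_id = f"{p.case_id}_hpf{i:04d}"
        tiles.append(tile)
        labels.append(annot)
    return CaseBundle(p.case_id, p.infected, counts, tiles, labels, p)


def split_dataset(
    n_items: int, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition ``range(n_items)`` into train/val/test index arrays.

    A seeded random permutation is cut at ``floor(f1 * n)`` and
    ``floor(f1 * n) + floor(f2 * n)``; the test set takes the remainder.
    With fractions 0.7/0.2/0.1 and n = 3,923 this gives 2,746/784/393.
    """
    if n_items < 0:
        raise ValidationError("n_items must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    perm = rng.permutation(n_items)
    f1, f2, _ = spec.fractions
    n_train = int(np.floor(f1 * n_items))
    n_val = int(np.floor(f2 * n_items))
    return (
        perm[:n_train],
        perm[n_train : n_train + n_val],
        perm[n_train + n_val :],
    )
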