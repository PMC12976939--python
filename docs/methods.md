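# Methods

## The diagnostic model

The package treats PJI diagnosis as a two-stage problem: (1) detect every
neutrophil on a scanned slide, (2) summarize the detections into a per-case
statistic and threshold it. The summary statistic is the **median
neutrophil count per high-powered field** over all HPF tiles of the slide;
a case is called *infected* when the median is at least 5 per HPF.

The threshold rule defaults to `median >= 5` (`ge`). The ≥ form is used
because the histological consensus criterion is "five or more per HPF" and
because published per-case tables classify medians of exactly 5 as
infected; a strict `gt` rule is available as a parameter.

Assumptions: every detection is a neutrophil regardless of location
(intravascular neutrophils are *not* excluded), every HPF tile of the slide
enters the median (edge tiles truncated at the slide boundary included — an
option excludes tiles under half the full area), and detections are
assigned to exactly one HPF by box-centre containment so no cell is counted
twice across tile borders.

## Geometry and calibration

Pixel boxes are half-open intervals `[x0, x1) × [y0, y1)`, which makes
integer-box areas exact and lets the HPF grid tile a slide without gaps or
overlaps (tile areas sum to the slide area exactly). IOU is computed on
continuous areas, the standard choice in detection evaluation.

The HPF is defined by physical calibration: a scanner resolution ρ (px/mm,
reference 4,050) and an HPF area A (mm², reference 0.2) give square tiles
of side `round(√A · ρ)` = 1,811 px at the reference values. Square tiles
are used because only the area of the optical field is specified; a square
of equal area is the natural raster analogue of the circular field.

Sliced inference uses windows of 512 px with 30% overlap: stride
`floor(512 · 0.7)` = 358 px, final offset clamped flush to the slide edge
so coverage is complete and edge windows stay full-size on slides at least
one window wide. Detections touching an interior window border are dropped
(the overlapping neighbour sees the object whole); duplicates in overlap
zones are removed by greedy NMS at IOU ≥ 0.5 keeping the higher-confidence
member. Merging is idempotent.

## Matching and metrics

Detections are matched to ground truth greedily in descending confidence;
each detection claims the unmatched truth box with the highest IOU
**strictly greater than** 0.5 (the threshold is a parameter). Unclaimed
detections are false positives; unclaimed truth boxes are false negatives.
On small instances with distinct IOUs this greedy assignment attains the
maximum-cardinality matching (verified against exhaustive search in the
tests); ties between equal IOUs can in principle diverge from the optimum,
which is the standard behaviour of confidence-ordered matching.

Precision/recall/F1 keep full precision internally; display rounding is
half-up to 2 decimals or whole percents, matching how such tables are
conventionally printed. Degenerate denominators (no detections, no truths)
are flagged `undefined` rather than silently zeroed, except F1 at
precision = recall = 0, which resolves to 0 as the harmonic-mean limit.

Interobserver agreement reuses the same machinery with one annotator as
"truth" and the other at uniform confidence, ties broken by descending IOU.
Consensus merging pairs two annotators' boxes at IOU ≥ 0.5 (greedy by
descending IOU), emits the coordinate-wise mean of each agreed pair, and
routes everything unmatched to per-annotator dispute lists — the automated
step only proposes; adjudication of disputes is a human task, and removal
of uncertain ground-truth boxes is an explicit exclusion list, never an
automated judgement.

## Exact McNemar test

Two paired binary classifiers are compared on their discordant counts
`b` (first positive only) and `c` (second positive only). Under marginal
homogeneity `b ~ Binomial(b + c, ½)`, so the exact two-sided p-value is
`min(1, 2·P(X ≤ min(b, c)))`, with `p = 1` when `b = c` (and when
`b + c = 0`). The implementation uses the scipy binomial CDF and is checked
in the tests against direct enumeration and against statsmodels' exact
McNemar. For each reference standard the discordant counts are taken from
the corresponding confusion table over the included (non-uncertain) cases.

Cases with an *uncertain* histology verdict appear in the confusion table
but are excluded from metric and McNemar computation by default — the
reading consistent with published confusion blocks whose three metrics
agree.

## Synthetic data: what it emulates, what it does not

`synthgen` produces H&E-like tiles: a light pink background, anucleate red
cells (pink discs with a paler centre), lymphocyte distractors (one large
round dark-purple nucleus), necrotic specks (small irregular dark
fragments), and the targets — neutrophil-like cells rendered as a lighter
cytoplasm disc containing 2–5 disjoint dark-purple lobes arranged on a
ring whose radius guarantees the lobes never merge. Default tile geometry
is 224 × 224 px with 40 × 40 px targets, the scale at which neutrophils
appear in 40× scanned histology. Gaussian luminance noise (σ = 4) is
added per pixel.

Placement is rejection sampling. Nucleated objects keep a minimum centre
separation of 1.1 × target size, which guarantees the reference detector's
lobe grouping can never chain two cells; when a tile is too crowded the
separation relaxes stepwise to a floor of 0.7 × target size (at which
ground-truth box IOUs still stay ≤ 0.3) before a capacity error is raised.
Crowded tiles can therefore undercount slightly, which never affects the
median-based diagnosis because such tiles lie far above threshold anyway.

Per-HPF target counts are drawn from a **negative binomial**
(mean m, dispersion θ; variance m + m²/θ) because neutrophil infiltrates
cluster into "hot spots" and are overdispersed relative to Poisson.
Defaults: m = 8 for infected and m = 2 for sterile cases, θ = 3 — means
that straddle the diagnostic threshold of 5 with a separation comparable
to real per-case medians, giving 200-HPF case medians of 6–8 vs 1–2.
Counts are truncated at 22 per tile so every tile remains renderable; the
truncation moves the infected mean from 8.00 to 7.92 (< 1.1%). Distractor
counts per tile are Poisson (lymphocytes 2, red cells 5, necrotic
fragments 1.5).

What the fixtures do **not** emulate: stain variation, texture, tissue
architecture, vessels, focus artefacts, and the full morphological
ambiguity of real sections. Passing the synthetic end-to-end tests shows
the *pipeline* (tiling, slicing, merging, counting, thresholding,
statistics) is correct, not that any detector generalizes to real tissue.

## Reference detector

The reference detector encodes the textbook morphology rather than learned
features: (1) threshold dark nuclear material at luminance < 120 (H&E
nuclei are dark purple; red cells and cytoplasm are far lighter),
(2) connected components with area ≥ 0.025 · scale² (rejects necrotic
specks), (3) single-linkage grouping of component centroids within
scale/2 into candidate cells, (4) score each candidate by lobe count
(2–5 favoured — one blob is a lymphocyte), total nuclear area relative to
the cell disc, and the fraction of light pixels on a sampled annulus
around the candidate (cytoplasm/background ring). Confidence is the
weighted sum (0.6/0.25/0.15) clipped to [0, 1]; the operating threshold
is 0.5. The emitted box is the grouped-lobe bounding box padded to at
least 0.9 × scale per side.

The detector is deterministic, satisfies the `DetectorContract` protocol,
and exists so that the pipeline is testable without trained weights; a
trained model plugs in through the same contract.

## Numerical choices

- `from_normalized` rounds x0/y0 half-up and derives x1 = x0 + round(w·W),
  keeping box widths stable under label round trips (half-pixel accuracy).
- Median and quartiles use linear interpolation between order statistics;
  integer counts can give half-valued medians, kept at full precision.
- Sub-seeds for per-tile reproducibility derive from
  `numpy.random.SeedSequence(case_seed).spawn(...)`, so any HPF tile can be
  regenerated independently; all generator outputs are pure functions of
  their parameters.
- Dataset splitting cuts a seeded permutation at `floor(f1·n)` and
  `floor(f1·n) + floor(f2·n)` with the remainder as the test set — the
  unique rule reproducing a 2,746/784/393 split of 3,923 at 0.7/0.2/0.1.
- Pixel inner loops (disc painting, luminance threshold, placement scan,
  annulus sampling) are numba-compiled; randomness stays in numpy so
  outputs are independent of the compilation path.

## Problem sizes

The end-to-end cohort simulation in the tests uses 20 cases of 200 HPF
tiles per seed across 50 seeds (1,000 simulated cases, 200,000 rendered
tiles); the acceptance script uses 2 × 20 cases at 200 HPFs plus 100
single tiles. Count-level simulations (no rendering) use 200–4,000 HPFs
per draw. These sizes give the label-recovery and distribution checks
comfortable statistical margins while keeping a full run on one CPU at
desk scale.

## Known limitations

- The reference detector is co-designed with the generator; its near-perfect
  synthetic scores say nothing about real H&E tissue.
- Greedy matching can differ from optimal assignment on exact IOU ties.
- Pyramidal slide formats are supported only through the mosaic/tile
  directory stand-in; a dedicated slide-reader backend can be layered on
  top of `wsi.plan_windows`/`make_hpf_grid`, which operate on dimensions,
  not file handles.
- The example cohort ships summary statistics only (per-HPF raw counts are
  not published), so cohort-level results are recomputed from medians, not
  from pixels.
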