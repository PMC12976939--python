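"""Detection-truth matching, metrics, curves, and interobserver agreement."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neutrocount.annot_io import AnnotationSet
from neutrocount.detect import Detection
from neutrocount.errors import ValidationError
from neutrocount.geometry import Box, iou, to_normalized
from neutrocount.matching import (
    confidence_precision_curve,
    interobserver,
    match,
    metrics,
    round_half_up,
)


def exhaustive_max_matching(dets, truths, thresh):
    """Oracle: maximum-cardinality one-to-one assignment above threshold."""
    edges = [
        (i, j)
        for i in range(len(dets))
        for j in range(len(truths))
        if iou(dets[i].box, truths[j]) > thresh
    ]
    best = 0
    for r in range(min(len(dets), len(truths)), 0, -1):
        for combo in itertools.combinations(edges, r):
            di = [e[0] for e in combo]
            tj = [e[1] for e in combo]
            if len(set(di)) == r and len(set(tj)) == r:
                return r
    return best


def random_instance(rng, n_max=8):
    nd = int(rng.integers(0, n_max + 1))
    nt = int(rng.integers(0, n_max + 1))
    dets = [
        Detection(
            Box(x, y, x + 10 + rng.uniform(0, 4), y + 10 + rng.uniform(0, 4)),
            float(rng.uniform(0.01, 1.0)),
        )
        for x, y in rng.uniform(0, 40, size=(nd, 2))
    ]
    truths = [Box(x, y, x + 12, y + 12) for x, y in rng.uniform(0, 40, size=(nt, 2))]
    return dets, truths


class TestMatch:
    def test_perfect_detections(self):
        truths = [Box(0, 0, 10, 10), Box(30, 30, 40, 40)]
        dets = [Detection(t, 0.9) for t in truths]
        m = match(dets, truths)
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)

    def test_no_detections_all_fn(self):
        m = match([], [Box(0, 0, 10, 10)] * 3)
        assert (m.tp, m.fp, m.fn) == (0, 0, 3)

    def test_greedy_claim_blocks_second_detection(self):
        truths = [Box(0, 0, 10, 10)]
        dets = [
            Detection(Box(0, 0, 10, 10), 0.9),
            Detection(Box(1, 1, 11, 11), 0.8),  # IOU ~0.68 but truth is taken
        ]
        m = match(dets, truths)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_strictly_greater_rule(self):
        # IOU exactly 0.5 must not match under the strict rule
        truths = [Box(0, 0, 10, 10)]
        dets = [Detection(Box(0, 0, 10, 5), 0.9)]
        assert iou(dets[0].box, truths[0]) == 0.5
        assert match(dets, truths, 0.5).tp == 0

    def test_conservation(self, rng):
        for _ in range(30):
            dets, truths = random_instance(rng)
            m = match(dets, truths)
            assert m.tp + m.fp == len(dets)
            assert m.tp + m.fn == len(truths)
            assert all(v > 0.5 for _, _, v in m.matched_pairs)

    def test_threshold_monotonicity(self, rng):
        for _ in range(20):
            dets, truths = random_instance(rng)
            tps = [match(dets, truths, t).tp for t in (0.2, 0.4, 0.6, 0.8)]
            assert tps == sorted(tps, reverse=True)

    def test_greedy_equals_exhaustive_on_small_instances(self, rng):
        """Greedy confidence-ordered matching attains the maximum-cardinality
        assignment whenever pairwise IOUs are distinct (random instances)."""
        checked = 0
        while checked < 60:
            dets, truths = random_instance(rng, n_max=6)
            ious = [
                iou(d.box, t)
                for d in dets
                for t in truths
            ]
            above = [v for v in ious if v > 0.5]
            if len(set(above)) != len(above):
                continue
            checked += 1
            assert match(dets, truths).tp == exhaustive_max_matching(dets, truths, 0.5)


class TestMetrics:
    def test_published_patch_counts(self):
        em = metrics(101, 22, 27)
        assert em.rounded() == (0.82, 0.79, 0.80)

    def test_mdt_block_counts(self):
        em = metrics(9, 1, 2)
        assert em.rounded() == (0.90, 0.82, 0.86)

    def test_all_zero_undefined(self):
        em = metrics(0, 0, 0)
        assert not (em.precision_defined or em.recall_defined or em.f1_defined)
        assert math.isnan(em.precision)

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(50):
            tp, fp, fn = (int(v) for v in rng.integers(1, 50, 3))
            em = metrics(tp, fp, fn)
            assert min(em.precision, em.recall) - 1e-12 <= em.f1 <= max(em.precision, em.recall) + 1e-12

    def test_round_half_up(self):
        assert round_half_up(0.825, 2) == 0.83
        assert round_half_up(0.815, 2) == 0.82  # repr keeps the stored value
        assert round_half_up(77.5, 0) == 78


class TestCurve:
    def test_threshold_zero_matches_unfiltered(self):
        truths = [Box(0, 0, 10, 10), Box(30, 0, 40, 10)]
        dets = [Detection(truths[0], 0.9), Detection(Box(60, 60, 70, 70), 0.3)]
        curve = confidence_precision_curve(dets, truths, [0.0, 0.5])
        m = match(dets, truths)
        assert curve[0][1] == pytest.approx(metrics(m.tp, m.fp, m.fn).precision)

    def test_perfect_detector_flat_at_one(self):
        truths = [Box(0, 0, 10, 10)]
        dets = [Detection(truths[0], 0.8)]
        curve = confidence_precision_curve(dets, truths, [0.0, 0.4, 0.8])
        assert all(p == 1.0 for _, p in curve)

    def test_non_decreasing_when_noise_has_lower_confidence(self):
        truths = [Box(i * 30, 0, i * 30 + 12, 12) for i in range(5)]
        dets = [Detection(t, 0.9) for t in truths] + [
            Detection(Box(i * 30, 100, i * 30 + 12, 112), 0.3) for i in range(4)
        ]
        curve = confidence_precision_curve(dets, truths, [0.0, 0.2, 0.5, 0.8])
        ps = [p for _, p in curve]
        assert ps == sorted(ps)
        assert ps[-1] == 1.0


class TestInterobserver:
    def make(self, boxes, w=200, h=200):
        return AnnotationSet("img", w, h, [to_normalized(b, w, h) for b in boxes])

    def test_identical_annotators(self):
        s = self.make([Box(0, 0, 20, 20), Box(50, 50, 80, 80)])
        em = interobserver(s, s)
        assert (em.precision, em.recall, em.f1) == (1.0, 1.0, 1.0)

    def test_disjoint_annotators_all_zero(self):
        a = self.make([Box(0, 0, 20, 20)])
        b = self.make([Box(100, 100, 120, 120)])
        em = interobserver(a, b)
        assert (em.precision, em.recall, em.f1) == (0.0, 0.0, 0.0)

    def test_partial_agreement_formulas(self):
        # 3 of 4 vs 5 boxes agree: precision 3/4, recall 3/5
        shared = [Box(i * 40, 0, i * 40 + 20, 20) for i in range(3)]
        a = self.make(shared + [Box(0, 100, 20, 120)])
        b = self.make(shared + [Box(60, 100, 80, 120), Box(120, 100, 140, 120)])
        em = interobserver(a, b)
        assert em.precision == pytest.approx(0.75)
        assert em.recall == pytest.approx(0.60)
        assert em.f1 == pytest.approx(2 / 3, abs=1e-3)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            interobserver(self.make([]), self.make([], w=50, h=50))
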