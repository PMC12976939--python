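"""Calibrated HPF tiling, window planning, and cross-window merging."""

import numpy as np
import pytest

from neutrocount.detect import Detection, filter_by_confidence
from neutrocount.errors import ValidationError
from neutrocount.geometry import Box
from neutrocount.pipeline import detect_sliced
from neutrocount.synthgen import TileParams, generate_tile
from neutrocount.wsi import (
    Calibration,
    hpf_side,
    make_hpf_grid,
    merge_window_detections,
    plan_windows,
)


class TestHpfSide:
    @pytest.mark.parametrize(
        "px_per_mm, area, expected",
        [(4050, 0.2, 1811), (1000, 1.0, 1000), (4050, 0.05, 906)],
    )
    def test_side_examples(self, px_per_mm, area, expected):
        assert hpf_side(Calibration(px_per_mm, area)) == expected

    def test_invalid_calibration(self):
        with pytest.raises(ValidationError):
            Calibration(px_per_mm=0)


class TestHpfGrid:
    def test_single_tile_slide(self):
        g = make_hpf_grid(1811, 1811)
        assert len(g.tiles) == 1
        assert g.tiles[0] == Box(0, 0, 1811, 1811)

    def test_truncated_edge_tiles(self):
        g = make_hpf_grid(4000, 2000)
        assert len(g.tiles) == 6  # 3 columns x 2 rows
        assert g.tiles[2] == Box(3622, 0, 4000, 1811)  # right edge truncated
        assert g.tiles[5].y1 == 2000

    def test_one_pixel_slide(self):
        g = make_hpf_grid(1, 1)
        assert g.tiles == [Box(0, 0, 1, 1)]

    def test_area_conservation(self, rng):
        for _ in range(20):
            w, h = (int(v) for v in rng.integers(1, 6000, 2))
            g = make_hpf_grid(w, h)
            assert sum(t.area for t in g.tiles) == w * h

    def test_tile_index_assigns_boundaries_right(self):
        g = make_hpf_grid(4000, 2000)
        assert g.tile_index(0, 0) == 0
        assert g.tile_index(1811, 0) == 1  # boundary goes to the next tile
        assert g.tile_index(3999, 1999) == 5


class TestPlanWindows:
    def test_exact_fit_single_window(self):
        plan = plan_windows(512, 512)
        assert [w for w in plan.windows] == [Box(0, 0, 512, 512)]

    def test_stride_and_edge_clamp(self):
        plan = plan_windows(1024, 512)
        xs = sorted({w.x0 for w in plan.windows})
        assert plan.stride == 358
        assert xs == [0, 358, 512]
        assert all(w.width == 512 for w in plan.windows)

    def test_zero_overlap_tiles_exactly(self):
        plan = plan_windows(1024, 512, overlap=0.0)
        assert sorted({w.x0 for w in plan.windows}) == [0, 512]

    def test_small_slide_truncated_window(self):
        plan = plan_windows(224, 224)
        assert plan.windows == [Box(0, 0, 224, 224)]

    def test_coverage_audit_random_dims(self, rng):
        """Every pixel column/row lies inside at least one window."""
        for _ in range(50):
            w, h = (int(v) for v in rng.integers(1, 3000, 2))
            plan = plan_windows(w, h)
            covx = np.zeros(w, dtype=int)
            covy = np.zeros(h, dtype=int)
            for win in plan.windows:
                covx[int(win.x0) : int(win.x1)] += 1
                covy[int(win.y0) : int(win.y1)] += 1
            assert covx.min() >= 1 and covy.min() >= 1
            # interior coverage doubles up along each axis when sliding
            if w > 512:
                assert covx.max() >= 2
            if h > 512:
                assert covy.max() >= 2

    def test_invalid_overlap(self):
        with pytest.raises(ValidationError):
            plan_windows(100, 100, overlap=1.0)


class TestMergeWindowDetections:
    def plan(self):
        return plan_windows(1024, 512)

    def test_single_window_pure_translation(self):
        plan = plan_windows(512, 512)
        d = Detection(Box(10, 10, 50, 50), 0.8)
        out = merge_window_detections({plan.windows[0]: [d]}, plan)
        assert out == [d]

    def test_duplicate_resolved_by_confidence(self):
        plan = self.plan()
        w0, w1 = plan.windows[0], plan.windows[1]  # offsets 0 and 358
        # same slide-coordinate object (400..440) seen by both windows
        d0 = Detection(Box(400, 10, 440, 50), 0.9)
        d1 = Detection(Box(42, 10, 82, 50), 0.7)
        out = merge_window_detections({w0: [d0], w1: [d1]}, plan)
        assert len(out) == 1
        assert out[0].confidence == 0.9
        assert out[0].box == Box(400, 10, 440, 50)

    def test_disjoint_objects_kept(self):
        plan = self.plan()
        w0 = plan.windows[0]
        a = Detection(Box(0, 0, 30, 30), 0.9)
        b = Detection(Box(100, 100, 130, 130), 0.4)
        out = merge_window_detections({w0: [a, b]}, plan)
        assert len(out) == 2
        assert [d.confidence for d in out] == [0.9, 0.4]  # sorted descending

    def test_merge_idempotent(self):
        plan = self.plan()
        w0, w1 = plan.windows[0], plan.windows[1]
        per = {
            w0: [Detection(Box(400, 10, 440, 50), 0.9), Detection(Box(5, 5, 45, 45), 0.6)],
            w1: [Detection(Box(42, 10, 82, 50), 0.7)],
        }
        once = merge_window_detections(per, plan)
        again = merge_window_detections({w0: once}, plan)
        assert again == once

    def test_detection_outside_window_rejected(self):
        plan = self.plan()
        with pytest.raises(ValidationError):
            merge_window_detections(
                {plan.windows[0]: [Detection(Box(500, 10, 600, 50), 0.5)]}, plan
            )


class TestSlicedEndToEnd:
    def test_planted_targets_recovered_across_windows(self):
        """k well-separated targets on a multi-window slide -> exactly k
        merged detections, over 100 seeded trials."""
        failures = 0
        for seed in range(100):
            k = 3 + seed % 5
            tile, annots = generate_tile(
                TileParams(
                    tile_w=700,
                    tile_h=700,
                    target_count=k,
                    distractor_counts={"lymphocyte": 0, "rbc": 8, "necrotic_fragment": 1},
                    seed=seed,
                )
            )
            dets, plan = detect_sliced(tile)
            assert len(plan.windows) == 4  # 2 x 2 overlapping windows
            kept = filter_by_confidence(dets, 0.5)
            if len(kept) != k:
                failures += 1
        assert failures == 0


class TestPartialTileFilter:
    def test_interior_tiles_kept_edges_dropped(self):
        from neutrocount.wsi import filter_partial_tiles

        g = make_hpf_grid(4000, 2000)  # 3 x 2 grid, side 1811
        kept = filter_partial_tiles(g, min_fill=0.5)
        # right-column tiles are 378 px wide (<50% area); bottom row is
        # 189 px tall; only the two full-height, full-width tiles survive
        assert kept == [0, 1]

    def test_min_fill_zero_keeps_all(self):
        from neutrocount.wsi import filter_partial_tiles

        g = make_hpf_grid(4000, 2000)
        assert filter_partial_tiles(g, min_fill=0.0) == list(range(6))
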