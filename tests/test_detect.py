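"""Tiled detection: tile planning, NMS vs brute force, reference detector,
occluder augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcamtools import detect
from mcamtools.detect import (
    BlobDetector,
    Detection,
    iou_matrix,
    nms,
    occluder_augment,
    plan_tiles,
    reference_blob_detector,
)


def brute_force_nms(boxes, scores, thr):
    """Independent O(n^2) reference: literal greedy definition."""
    boxes = np.asarray(boxes, float)
    order = sorted(range(len(boxes)), key=lambda i: (-scores[i], i))
    kept = []
    for i in order:
        ok = True
        for j in kept:
            # IoU from scratch
            ix0 = max(boxes[i][0], boxes[j][0])
            iy0 = max(boxes[i][1], boxes[j][1])
            ix1 = min(boxes[i][2], boxes[j][2])
            iy1 = min(boxes[i][3], boxes[j][3])
            inter = max(ix1 - ix0, 0) * max(iy1 - iy0, 0)
            ai = (boxes[i][2] - boxes[i][0]) * (boxes[i][3] - boxes[i][1])
            aj = (boxes[j][2] - boxes[j][0]) * (boxes[j][3] - boxes[j][1])
            if inter / (ai + aj - inter) > thr:
                ok = False
                break
        if ok:
            kept.append(i)
    return sorted(kept)


def random_boxes(rng, n, extent=200, max_side=60):
    x0 = rng.uniform(0, extent - 1, n)
    y0 = rng.uniform(0, extent - 1, n)
    w = rng.uniform(1, max_side, n)
    h = rng.uniform(1, max_side, n)
    return np.stack([x0, y0, x0 + w, y0 + h], axis=1)


class TestPlanTiles:
    def test_enumerated_origins_1000_512_384(self):
        plan = plan_tiles((1000, 1000), 512, 384)
        origins = sorted({t[0] for t in plan.tiles})
        assert origins == [0, 384, 488]
        assert len(plan.tiles) == 9

    def test_tile_larger_than_mosaic_gives_single_clamped_tile(self):
        plan = plan_tiles((300, 200), 512, 384)
        assert plan.tiles == [(0, 0)]
        assert plan.tile_px == (300, 200)

    def test_complete_coverage_and_overlap_band(self):
        plan = plan_tiles((700, 500), 256, 192)
        cover = np.zeros((500, 700), dtype=int)
        tw, th = plan.tile_px
        for x, y in plan.tiles:
            cover[y : y + th, x : x + tw] += 1
        assert (cover >= 1).all()
        # interior pixels well away from the mosaic edge sit in >= 2 tiles
        # along each overlapped axis
        assert (cover[200:300, 250:450] >= 2).any()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            plan_tiles((100, 100), 64, 0)
        with pytest.raises(ValueError):
            plan_tiles((100, 100), 0, 10)
        with pytest.raises(ValueError):
            plan_tiles((100, 100), 64, 128)  # stride > tile


class TestNms:
    def test_identical_boxes_keep_higher_score_then_lower_index(self):
        boxes = [(0, 0, 10, 10), (0, 0, 10, 10)]
        assert nms(boxes, [0.5, 0.9], 0.5) == [1]
        assert nms(boxes, [0.7, 0.7], 0.5) == [0]  # tie -> lower index

    def test_disjoint_boxes_all_kept(self):
        boxes = [(0, 0, 10, 10), (20, 20, 30, 30), (50, 0, 60, 10)]
        assert nms(boxes, [0.1, 0.9, 0.5], 0.0) == [0, 1, 2]

    def test_threshold_one_keeps_non_duplicates(self):
        rng = np.random.default_rng(1)
        boxes = random_boxes(rng, 50)
        kept = nms(boxes, rng.uniform(size=50), 1.0)
        assert kept == list(range(50))

    def test_matches_brute_force_on_200_random_boxes(self):
        rng = np.random.default_rng(7)
        boxes = random_boxes(rng, 200)
        scores = rng.uniform(size=200)
        assert nms(boxes, scores, 0.5) == brute_force_nms(boxes, scores, 0.5)

    @settings(deadline=None, max_examples=60)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.integers(min_value=1, max_value=40),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_matches_brute_force_property(self, seed, n, thr):
        rng = np.random.default_rng(seed)
        boxes = random_boxes(rng, n)
        scores = rng.uniform(size=n)
        assert nms(boxes, scores, thr) == brute_force_nms(boxes, scores, thr)

    def test_malformed_boxes_rejected(self):
        with pytest.raises(ValueError):
            nms([(10, 0, 0, 10)], [0.5], 0.5)
        with pytest.raises(ValueError):
            nms([(0, 0, 1, 1)], [0.5, 0.6], 0.5)


class TestReferenceDetector:
    def test_single_dark_gaussian_blob_boxed(self):
        yy, xx = np.mgrid[0:128, 0:128]
        img = 0.9 - 0.5 * np.exp(-((yy - 60) ** 2 + (xx - 70) ** 2) / (2 * 8**2))
        boxes, scores = reference_blob_detector(img, (8, 24), "dark", 0.1)
        assert len(boxes) == 1
        x0, y0, x1, y1 = boxes[0]
        assert x0 < 70 < x1 and y0 < 60 < y1
        assert scores[0] == pytest.approx(1.0)

    def test_flat_image_gives_no_boxes(self):
        boxes, scores = reference_blob_detector(np.full((64, 64), 0.7), (4, 16), "dark", 0.05)
        assert len(boxes) == 0

    def test_two_blobs_resolved_when_far_merged_when_close(self):
        def scene(sep):
            yy, xx = np.mgrid[0:200, 0:200]
            img = np.full((200, 200), 0.9)
            for dx in (-sep / 2, sep / 2):
                img -= 0.5 * np.exp(-((yy - 100) ** 2 + (xx - 100 - dx) ** 2) / (2 * 8**2))
            return img

        far, _ = reference_blob_detector(scene(5 * 8), (8, 24), "dark", 0.1)
        near, _ = reference_blob_detector(scene(0.8 * 8), (8, 24), "dark", 0.1)
        assert len(far) == 2
        assert len(near) == 1  # documented merge behavior below ~1 sigma

    def test_empty_scale_range_rejected(self):
        with pytest.raises(ValueError):
            reference_blob_detector(np.zeros((32, 32)), (10, 5), "dark", 0.1)


class TestDetectTiled:
    def test_boundary_straddling_object_detected_exactly_once(self):
        # dark disc centered exactly on the boundary between two tiles
        yy, xx = np.mgrid[0:256, 0:512]
        img = 0.9 - 0.6 * ((xx - 256) ** 2 + (yy - 128) ** 2 < 12**2)
        plan = plan_tiles((512, 256), 256, 192)
        dets, failures = detect.detect_tiled(img, BlobDetector(scale_range_px=(8, 24), threshold=0.1), plan)
        assert not failures
        assert len(dets) == 1
        cx, cy = dets[0].center
        assert cx == pytest.approx(256, abs=6)
        assert cy == pytest.approx(128, abs=6)

    def test_blank_mosaic_gives_empty_list(self):
        plan = plan_tiles((400, 300), 256, 192)
        dets, _ = detect.detect_tiled(np.full((300, 400), 0.8), BlobDetector(), plan)
        assert dets == []

    def test_25_separated_discs_all_recovered_within_5px(self):
        rng = np.random.default_rng(3)
        img = np.full((600, 800), 0.88)
        yy, xx = np.mgrid[0:600, 0:800]
        centers = []
        while len(centers) < 25:
            c = (rng.uniform(30, 770), rng.uniform(30, 570))
            if all(np.hypot(c[0] - a, c[1] - b) > 60 for a, b in centers):
                centers.append(c)
        for cx, cy in centers:
            img -= 0.5 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 6**2))
        plan = plan_tiles((800, 600), 256, 192)
        dets, _ = detect.detect_tiled(img, BlobDetector(scale_range_px=(6, 18), threshold=0.1), plan)
        assert len(dets) == 25
        for cx, cy in centers:
            d = min(np.hypot(d.center[0] - cx, d.center[1] - cy) for d in dets)
            assert d <= 5.0

    def test_stride_invariance_of_final_boxes(self):
        rng = np.random.default_rng(5)
        img = np.full((400, 600), 0.85)
        yy, xx = np.mgrid[0:400, 0:600]
        for cx, cy in [(100, 100), (300, 250), (500, 120), (220, 330)]:
            img -= 0.5 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 7**2))
        det = BlobDetector(scale_range_px=(6, 18), threshold=0.1)
        results = []
        for stride in (160, 200, 256):
            plan = plan_tiles((600, 400), 256, stride)
            dets, _ = detect.detect_tiled(img, det, plan)
            results.append(sorted([tuple(round(v) for v in d.box_px) for d in dets]))
        for r in results[1:]:
            assert len(r) == len(results[0])
            for b1, b0 in zip(r, results[0]):
                assert max(abs(x - y) for x, y in zip(b1, b0)) <= 1

    def test_partial_tile_failures_recorded_total_failure_raises(self):
        calls = {"n": 0}

        def flaky(tile):
            calls["n"] += 1
            if calls["n"] % 2 == 0:
                raise RuntimeError("boom")
            return np.zeros((0, 4)), np.zeros(0)

        plan = plan_tiles((400, 400), 256, 192)
        dets, failures = detect.detect_tiled(np.zeros((400, 400)), flaky, plan)
        assert len(failures) == len(plan.tiles) // 2

        def always_fails(tile):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError):
            detect.detect_tiled(np.zeros((400, 400)), always_fails, plan)


class TestOccluderAugment:
    def _crops(self):
        img = np.full((40, 40), 0.2)
        mask = np.zeros((40, 40), bool)
        mask[5:35, 10:30] = True
        return [(img, mask)]

    def test_zero_pastes_leaves_background_untouched(self):
        bg = np.full((200, 200), 0.9)
        out, boxes = occluder_augment(self._crops(), bg, 0, (0.0, 0.3), seed=1)
        assert np.array_equal(out, bg)
        assert boxes == []

    def test_pairwise_iou_within_requested_range(self):
        bg = np.full((300, 300), 0.9)
        out, boxes = occluder_augment(self._crops(), bg, 2, (0.2, 0.4), seed=2)
        iou = iou_matrix([boxes[0]], [boxes[1]])[0, 0]
        assert 0.2 <= iou <= 0.4
        assert not np.array_equal(out, bg)

    def test_same_seed_identical_composite(self):
        bg = np.full((300, 300), 0.9)
        out1, b1 = occluder_augment(self._crops(), bg, 3, (0.1, 0.5), seed=9)
        out2, b2 = occluder_augment(self._crops(), bg, 3, (0.1, 0.5), seed=9)
        assert np.array_equal(out1, out2)
        assert b1 == b2

    def test_unsatisfiable_constraint_raises(self):
        bg = np.full((60, 60), 0.9)
        with pytest.raises(RuntimeError):
            occluder_augment(self._crops(), bg, 3, (0.97, 0.99), seed=0, max_attempts=50)


class TestDetectionType:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Detection(box_px=(10, 0, 5, 10), score=0.5)
        with pytest.raises(ValueError):
            Detection(box_px=(0, 0, 5, 5), score=1.5)
        d = Detection(box_px=(0, 0, 10, 20), score=0.5)
        assert d.center == (5.0, 10.0)
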