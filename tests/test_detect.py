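"""Window proposal, normalization, NMS and matching against brute force."""

import numpy as np
import pytest

from tscnna.detect import (
    CandidateWindow,
    Detection,
    DetectionConfig,
    classify_windows,
    filter_and_suppress,
    iou,
    match_detections,
    normalize_window,
    propose_windows,
    window_grid_count,
)
from tscnna.io import BoundingBoxAnnotation
from tscnna.model import ArchitectureConfig, build_model, forward

TINY = ArchitectureConfig(
    input_side=16, stem_channels=2, conv2_channels=4, conv3_channels=4,
    conv4_channels=4, tail_channels=6, num_classes=2, attention_ratio=2,
)


class TestProposeWindows:
    def test_64_image_scale_32_full_stride_gives_4(self):
        windows = propose_windows(64, 64, (32,), 1.0)
        got = {(w.x_min, w.y_min) for w in windows}
        assert got == {(0, 0), (0, 32), (32, 0), (32, 32)}

    def test_scale_equal_to_image_gives_single_window(self):
        windows = propose_windows(64, 64, (64,), 1.0)
        assert len(windows) == 1
        w = windows[0]
        assert (w.x_min, w.y_min, w.x_max, w.y_max) == (0, 0, 64, 64)

    def test_count_matches_exhaustive_enumeration(self):
        for height, width, scales, frac in [
            (96, 96, (32, 48), 0.5),
            (50, 70, (16, 32), 0.25),
            (33, 47, (10,), 0.7),
        ]:
            windows = propose_windows(height, width, scales, frac)
            # enumeration oracle: walk starts, add flush edge, dedupe
            want = 0
            for s in scales:
                step = max(1, round(frac * s))
                xs = sorted(set(list(range(0, width - s + 1, step)) + [width - s]))
                ys = sorted(set(list(range(0, height - s + 1, step)) + [height - s]))
                want += len(xs) * len(ys)
            assert len(windows) == want
            for s in scales:
                step = max(1, round(frac * s))
                axis = window_grid_count(width, s, step)
                assert axis == len(sorted(set(list(range(0, width - s + 1, step)) + [width - s])))

    def test_every_pixel_covered_at_every_scale(self):
        height, width = 40, 56
        for s in (8, 16, 24):
            cover = np.zeros((height, width), dtype=bool)
            for w in propose_windows(height, width, (s,), 0.5):
                cover[w.y_min : w.y_max, w.x_min : w.x_max] = True
            assert cover.all()

    def test_scale_exceeding_image_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            propose_windows(30, 30, (32,), 0.5)


class TestNormalizeWindow:
    def test_output_is_exactly_input_side(self, rng):
        img = rng.integers(0, 256, size=(60, 80, 3), dtype=np.uint8)
        out = normalize_window(img, (5, 10, 53, 50), side=32)
        assert out.shape == (32, 32, 3)

    def test_already_32_box_passes_through(self, rng):
        img = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        out = normalize_window(img, (8, 8, 40, 40), side=32)
        np.testing.assert_array_equal(out, img[8:40, 8:40].astype(float))

    def test_constant_region_stays_constant(self):
        img = np.full((64, 64, 3), 120, dtype=np.uint8)
        out = normalize_window(img, (0, 0, 64, 64), side=32)
        np.testing.assert_allclose(out, 120.0)

    def test_empty_box_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            normalize_window(rng.integers(0, 255, (10, 10, 3)), (4, 4, 4, 8))


class TestClassifyWindows:
    def test_empty_window_list(self):
        model = build_model(TINY, seed=0)
        out = classify_windows(model, np.zeros((32, 32, 3), dtype=np.uint8), [], side=16)
        assert out.shape == (0, 3)

    def test_duplicated_window_rows_identical(self, rng):
        model = build_model(TINY, seed=0)
        img = rng.integers(0, 256, size=(48, 48, 3), dtype=np.uint8)
        w = CandidateWindow(4, 4, 28, 28, 0)
        rows = classify_windows(model, img, [w, w], side=16)
        np.testing.assert_array_equal(rows[0], rows[1])

    def test_rows_match_single_forward_calls(self, rng):
        model = build_model(TINY, seed=1)
        img = rng.integers(0, 256, size=(48, 48, 3), dtype=np.uint8)
        windows = propose_windows(48, 48, (16, 24), 0.5)[:7]
        rows = classify_windows(model, img, windows, side=16)
        for w, row in zip(windows, rows):
            crop = normalize_window(img, w, side=16) / 255.0
            single = forward(model, crop.astype(np.float32))[0]
            np.testing.assert_allclose(row, single, atol=1e-5)


class TestIoU:
    def test_identical_boxes_give_one(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes_give_zero(self):
        assert iou((0, 0, 4, 4), (10, 10, 14, 14)) == 0.0

    def test_symmetric_and_bounded(self, rng):
        for _ in range(100):
            a = tuple(np.sort(rng.integers(0, 30, size=2))) + tuple(np.sort(rng.integers(31, 60, size=2)))
            a = (a[0], a[2], a[1] + 1, a[3] + 1)
            b0 = rng.integers(0, 30, size=2)
            b = (int(b0[0]), int(b0[1]), int(b0[0] + rng.integers(1, 20)), int(b0[1] + rng.integers(1, 20)))
            assert iou(a, b) == iou(b, a)
            assert 0.0 <= iou(a, b) <= 1.0
            if iou(a, b) == 1.0:
                assert a == b


def brute_force_nms(boxes, scores, threshold):
    """O(n²) reference suppression: keep a box iff no higher-scored kept box
    overlaps it at IoU ≥ threshold."""
    order = sorted(range(len(boxes)), key=lambda i: -scores[i])
    kept = []
    for i in order:
        if all(iou(boxes[i], boxes[j]) < threshold for j in kept):
            kept.append(i)
    return {boxes[i] for i in kept}


class TestFilterAndSuppress:
    CLASSES = ("a", "b", "bg")

    def _window(self, box):
        return CandidateWindow(*box, 0)

    def test_all_background_gives_empty(self):
        windows = [self._window((0, 0, 8, 8)), self._window((8, 8, 16, 16))]
        probs = np.array([[0.1, 0.1, 0.8], [0.0, 0.2, 0.8]])
        assert filter_and_suppress(windows, probs, self.CLASSES, 2) == []

    def test_identical_boxes_keep_highest_score(self):
        w = self._window((4, 4, 20, 20))
        probs = np.array([[0.9, 0.05, 0.05], [0.8, 0.1, 0.1]])
        out = filter_and_suppress([w, w], probs, self.CLASSES, 2)
        assert len(out) == 1
        assert out[0].score == pytest.approx(0.9)

    def test_low_scores_dropped(self):
        w = self._window((0, 0, 10, 10))
        probs = np.array([[0.45, 0.25, 0.3]])
        assert filter_and_suppress([w], probs, self.CLASSES, 2, score_threshold=0.5) == []

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            n = 20
            boxes = []
            for _ in range(n):
                x0, y0 = rng.integers(0, 40, size=2)
                boxes.append((int(x0), int(y0), int(x0 + rng.integers(4, 25)), int(y0 + rng.integers(4, 25))))
            scores = rng.uniform(0.5, 0.99, size=n)
            # single pest class so NMS is exercised directly
            probs = np.zeros((n, 2))
            probs[:, 0] = scores
            probs[:, 1] = 1 - scores
            windows = [self._window(b) for b in boxes]
            out = filter_and_suppress(windows, probs, ("a", "bg"), 1, 0.5, 0.3)
            got = {(d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max) for d in out}
            assert got == brute_force_nms(boxes, scores, 0.3)

    def test_output_is_iou_antichain_per_class(self, rng):
        n = 30
        boxes = []
        for _ in range(n):
            x0, y0 = rng.integers(0, 50, size=2)
            boxes.append((int(x0), int(y0), int(x0 + rng.integers(5, 30)), int(y0 + rng.integers(5, 30))))
        probs = rng.uniform(0.1, 1.0, size=(n, 3))
        probs /= probs.sum(axis=1, keepdims=True)
        out = filter_and_suppress([self._window(b) for b in boxes], probs, self.CLASSES, 2, 0.1, 0.3)
        for i, a in enumerate(out):
            for b in out[i + 1 :]:
                if a.box.species == b.box.species:
                    pa = (a.box.x_min, a.box.y_min, a.box.x_max, a.box.y_max)
                    pb = (b.box.x_min, b.box.y_min, b.box.x_max, b.box.y_max)
                    assert iou(pa, pb) < 0.3


def brute_force_matching(detections, truths, threshold):
    """Greedy reference: score-ordered detections claim their best unclaimed
    same-class truth at IoU ≥ threshold."""
    taken = set()
    tp = 0
    for det in sorted(detections, key=lambda d: -d.score):
        best, best_iou = None, threshold
        for j, t in enumerate(truths):
            if j in taken or t.species != det.box.species:
                continue
            v = iou(
                (det.box.x_min, det.box.y_min, det.box.x_max, det.box.y_max),
                (t.x_min, t.y_min, t.x_max, t.y_max),
            )
            if v >= best_iou:
                best, best_iou = j, v
        if best is not None:
            taken.add(best)
            tp += 1
    return tp


class TestMatchDetections:
    def test_perfect_detections(self):
        truths = [BoundingBoxAnnotation("a", 0, 0, 10, 10), BoundingBoxAnnotation("b", 20, 20, 30, 30)]
        dets = [Detection(t, 0.9) for t in truths]
        result = match_detections(dets, truths, 0.3)
        assert result["precision"] == 1.0 and result["recall"] == 1.0
        assert result["fn"] == 0 and result["fp"] == 0

    def test_no_detections_counts_all_misses(self):
        truths = [BoundingBoxAnnotation("a", 0, 0, 10, 10)] * 0 + [
            BoundingBoxAnnotation("a", i * 12, 0, i * 12 + 10, 10) for i in range(3)
        ]
        result = match_detections([], truths, 0.3)
        assert result["recall"] == 0.0 and result["fn"] == 3

    def test_class_mismatch_never_matches(self):
        truth = [BoundingBoxAnnotation("a", 0, 0, 10, 10)]
        det = [Detection(BoundingBoxAnnotation("b", 0, 0, 10, 10), 0.9)]
        result = match_detections(det, truth, 0.3)
        assert result["tp"] == 0 and result["fp"] == 1 and result["fn"] == 1

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            truths = [
                BoundingBoxAnnotation(
                    str(rng.choice(["a", "b"])),
                    int(x0), int(y0), int(x0 + rng.integers(4, 15)), int(y0 + rng.integers(4, 15)),
                )
                for x0, y0 in rng.integers(0, 40, size=(rng.integers(1, 5), 2))
            ]
            dets = [
                Detection(
                    BoundingBoxAnnotation(
                        str(rng.choice(["a", "b"])),
                        int(x0), int(y0), int(x0 + rng.integers(4, 15)), int(y0 + rng.integers(4, 15)),
                    ),
                    float(rng.uniform(0.5, 0.99)),
                )
                for x0, y0 in rng.integers(0, 40, size=(rng.integers(0, 6), 2))
            ]
            result = match_detections(dets, truths, 0.3)
            assert result["tp"] == brute_force_matching(dets, truths, 0.3)
            assert result["fp"] == len(dets) - result["tp"]
            assert result["fn"] == len(truths) - result["tp"]


class TestDetectionConfig:
    def test_bad_stride_rejected(self):
        with pytest.raises(ValueError):
            DetectionConfig(stride_fraction=0.0)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            DetectionConfig(score_threshold=1.5)

    def test_score_range_enforced_on_detection(self):
        with pytest.raises(ValueError):
            Detection(BoundingBoxAnnotation("a", 0, 0, 4, 4), 1.5)
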