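"""Detection matching, P/R/F1, AP against a brute-force sweep, count metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedstand.dataset_io import write_yolo_labels
from seedstand.evaluation import (
    MatchResult,
    average_precision,
    box_iou,
    count_metrics,
    detection_metrics,
    match_detections,
    mean_average_precision,
    score_prediction_files,
    yolo_to_pixel_box,
)


def random_instance(rng, max_preds=10):
    """One small detection problem: boxes on a 100×100 canvas."""
    n_gt = int(rng.integers(1, 6))
    n_pred = int(rng.integers(0, max_preds + 1))

    def rand_box():
        x1 = rng.uniform(0, 80)
        y1 = rng.uniform(0, 80)
        return (x1, y1, x1 + rng.uniform(5, 20), y1 + rng.uniform(5, 20))

    gts = [rand_box() for _ in range(n_gt)]
    preds = []
    for _ in range(n_pred):
        if rng.random() < 0.6 and gts:  # jittered copy of a gt box
            x1, y1, x2, y2 = gts[int(rng.integers(n_gt))]
            dx, dy = rng.uniform(-4, 4, size=2)
            preds.append((x1 + dx, y1 + dy, x2 + dx, y2 + dy))
        else:
            preds.append(rand_box())
    confs = rng.random(n_pred)  # distinct with probability 1
    return preds, list(confs), gts


def brute_force_ap(preds, confs, gts, iou_threshold=0.5):
    """Enumerate every confidence cutoff, rebuild the PR point at each, and
    integrate the stepwise precision envelope directly."""
    n_gt = len(gts)
    if n_gt == 0 or not preds:
        return 0.0
    order = sorted(range(len(preds)), key=lambda i: -confs[i])
    points = []
    for k in range(1, len(order) + 1):  # cutoff after the k best predictions
        kept = order[:k]
        matched = set()
        tp = 0
        for i in kept:
            best_j, best_iou = -1, 0.0
            for j, gt in enumerate(gts):
                if j in matched:
                    continue
                iou = box_iou(preds[i], gt)
                if iou >= iou_threshold and iou > best_iou:
                    best_j, best_iou = j, iou
            if best_j >= 0:
                matched.add(best_j)
                tp += 1
        points.append((tp / n_gt, tp / k))
    ap = 0.0
    prev_r = 0.0
    for r, _p in sorted(points):
        if r > prev_r:
            envelope = max(p2 for r2, p2 in points if r2 >= r)
            ap += (r - prev_r) * envelope
            prev_r = r
    return ap


class TestMatching:
    def test_identical_box_is_tp(self):
        m = match_detections([(0, 0, 10, 10)], [(0, 0, 10, 10)])
        assert (m.TP, m.FP, m.FN) == (1, 0, 0)
        assert m.pairs[0][2] == 1.0

    def test_double_detection_one_to_one(self):
        gt = [(0, 0, 10, 10)]
        preds = [(0, 0, 10, 10), (1, 1, 11, 11)]
        m = match_detections(preds, gt, confidences=[0.9, 0.8])
        assert (m.TP, m.FP, m.FN) == (1, 1, 0)

    def test_disjoint_boxes_miss(self):
        m = match_detections([(0, 0, 5, 5)], [(50, 50, 60, 60)])
        assert (m.TP, m.FP, m.FN) == (0, 1, 1)

    def test_malformed_box_raises(self):
        with pytest.raises(ValueError):
            match_detections([(10, 10, 5, 5)], [(0, 0, 5, 5)])

    def test_higher_confidence_matches_first(self):
        gt = [(0, 0, 10, 10)]
        preds = [(2, 2, 12, 12), (0, 0, 10, 10)]
        m = match_detections(preds, gt, confidences=[0.2, 0.9])
        assert m.pairs[0][0] == 1  # the exact, higher-confidence box wins


class TestDetectionMetrics:
    def test_hand_computed_case(self):
        p, r, f1 = detection_metrics(MatchResult(TP=90, FP=10, FN=10, pairs=[]))
        assert (p, r, f1) == (0.9, 0.9, pytest.approx(0.9))

    def test_empty_prediction_convention(self):
        assert detection_metrics(MatchResult(0, 0, 5, [])) == (0.0, 0.0, 0.0)

    def test_perfect(self):
        assert detection_metrics(MatchResult(1, 0, 0, [])) == (1.0, 1.0, 1.0)


class TestAveragePrecision:
    def test_single_perfect_prediction(self):
        ap = average_precision([("a", (0, 0, 10, 10), 0.9)], {"a": [(0, 0, 10, 10)]})
        assert ap == 1.0

    def test_mean_over_two_classes(self):
        gts = {
            0: {"a": [(0, 0, 10, 10)]},
            1: {"a": [(20, 20, 30, 30), (40, 40, 50, 50)]},
        }
        preds = {
            0: [("a", (0, 0, 10, 10), 0.9)],
            1: [("a", (20, 20, 30, 30), 0.8), ("a", (0, 0, 5, 5), 0.7)],
        }
        # class 0: AP 1; class 1: one of two gts found, one FP → AP 0.5
        mAP, per_class = mean_average_precision(preds, gts)
        assert per_class[0] == 1.0
        assert per_class[1] == 0.5
        assert mAP == 0.75

    def test_unknown_class_raises(self):
        with pytest.raises(ValueError):
            mean_average_precision({5: []}, {0: {}})

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            preds, confs, gts = random_instance(rng)
            triples = [("img", b, c) for b, c in zip(preds, confs)]
            ap = average_precision(triples, {"img": gts})
            assert ap == pytest.approx(brute_force_ap(preds, confs, gts), abs=1e-12)
            assert 0.0 <= ap <= 1.0


class TestCountMetrics:
    def test_perfect_predictions(self):
        s = count_metrics([10, 20, 30], [10, 20, 30])
        assert (s.R2, s.RMSE, s.RRMSE_pct) == (1.0, 0.0, 0.0)

    def test_hand_computed_case(self):
        s = count_metrics([10, 20, 30], [12, 18, 33])
        assert s.RMSE == pytest.approx(np.sqrt(17 / 3), abs=1e-4)
        assert s.R2 == pytest.approx(1 - 17 / 200, abs=1e-12)
        assert s.RRMSE_pct == pytest.approx(100 * np.sqrt(17 / 3) / 20, abs=1e-4)

    def test_constant_prediction_scores_zero(self):
        s = count_metrics([10, 20, 30], [20, 20, 20])
        assert s.R2 == 0.0

    def test_constant_truth_raises(self):
        with pytest.raises(ValueError):
            count_metrics([5, 5, 5], [4, 5, 6])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            count_metrics([1, 2], [1, 2, 3])

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 1000))
    def test_permutation_invariance(self, seed):
        r = np.random.default_rng(seed)
        y = r.integers(10, 100, size=12)
        if np.unique(y).size < 2:
            y[0] += 5
        x = y + r.integers(-5, 6, size=12)
        perm = r.permutation(12)
        a = count_metrics(y, x)
        b = count_metrics(y[perm], x[perm])
        assert a.R2 == pytest.approx(b.R2)
        assert a.RMSE == pytest.approx(b.RMSE)
        assert a.RRMSE_pct == pytest.approx(b.RRMSE_pct)


class TestPredictionFiles:
    def test_scores_external_yolo_files(self, tmp_path, rng):
        h, w = 100, 200
        gt_boxes = [(0, 0.25, 0.25, 0.1, 0.2), (0, 0.7, 0.6, 0.1, 0.1)]
        pred_boxes = [
            (0, 0.25, 0.25, 0.1, 0.2, 0.9),  # exact hit
            (0, 0.05, 0.9, 0.05, 0.05, 0.4),  # false positive
        ]
        gt_path = tmp_path / "img1.txt"
        pred_path = tmp_path / "img1_pred.txt"
        write_yolo_labels(gt_path, gt_boxes)
        write_yolo_labels(pred_path, pred_boxes)
        df = score_prediction_files([pred_path], [gt_path], [(h, w)])
        per_image = df.iloc[0]
        assert (per_image.TP, per_image.FP, per_image.FN) == (1, 1, 1)
        pooled = df.iloc[-1]
        assert pooled.P == 0.5 and pooled.R == 0.5
        assert 0.0 <= pooled.AP50 <= 1.0

    def test_yolo_to_pixel_box_roundtrip(self):
        box = yolo_to_pixel_box((0, 0.2, 0.2, 0.2, 0.2), 100, 100)
        assert box == pytest.approx((10.0, 10.0, 30.0, 30.0))
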