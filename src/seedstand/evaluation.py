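"""Detection and counting metrics.

Detection quality is scored by greedy one-to-one matching at an IoU
threshold (0.5 by default): predictions are visited in descending
confidence, each taking the unmatched ground-truth box of highest IoU at
or above the threshold.  Matched predictions are true positives (TP),
the rest false positives (FP), unmatched ground truths false negatives
(FN), giving

    P = TP / (TP + FP),   R = TP / (TP + FN),   F1 = 2PR / (P + R),

with the 0/0 cases defined as 0 so batch evaluation never fails.  Average
precision sweeps the precision–recall curve over descending confidence and
integrates the all-point precision envelope; mAP averages AP over classes.

Counting quality over a set of images compares predicted counts X_i with
true counts Y_i:

    R²    = 1 − Σ(Y_i − X_i)² / Σ(Y_i − Ȳ)²
    RMSE  = sqrt(Σ(Y_i − X_i)² / n)
    RRMSE = RMSE / Ȳ   (reported as a percentage)

Boxes are half-open pixel rectangles (x_min, y_min, x_max, y_max);
normalized YOLO coordinates are converted through the image size before
matching.  YOLO-format prediction files (with a sixth confidence column)
produced by any external detector can be scored against label files with
:func:`score_prediction_files`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset_io

Box = tuple[float, float, float, float]


def box_iou(a: Box, b: Box) -> float:
    """Intersection over union of two half-open pixel boxes."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    if ax2 <= ax1 or ay2 <= ay1 or bx2 <= bx1 or by2 <= by1:
        raise ValueError(f"malformed box (non-positive extent): {a} / {b}")
    ix = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    iy = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = ix * iy
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


@dataclass
class MatchResult:
    TP: int
    FP: int
    FN: int
    pairs: list[tuple[int, int, float]]  # (pred_idx, gt_idx, iou)


def match_detections(
    pred_boxes: list[Box],
    gt_boxes: list[Box],
    confidences: list[float] | None = None,
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground truths.

    Predictions are processed in descending confidence (input order for
    ties or when confidences are omitted); each takes the unmatched ground
    truth of highest IoU >= threshold.
    """
    n_pred = len(pred_boxes)
    if confidences is None:
        order = list(range(n_pred))
    else:
        order = sorted(range(n_pred), key=lambda i: -confidences[i])
    matched_gt: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for i in order:
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(gt_boxes):
            if j in matched_gt:
                continue
            iou = box_iou(pred_boxes[i], gt)
            if iou >= iou_threshold and iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0:
            matched_gt.add(best_j)
            pairs.append((i, best_j, best_iou))
    tp = len(pairs)
    return MatchResult(TP=tp, FP=n_pred - tp, FN=len(gt_boxes) - tp, pairs=pairs)


def detection_metrics(match: MatchResult) -> tuple[float, float, float]:
    """Precision, recall and F1 from match counts (0/0 cases are 0)."""
    tp, fp, fn = match.TP, match.FP, match.FN
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def average_precision(
    predictions: list[tuple[str, Box, float]],
    ground_truths: dict[str, list[Box]],
    iou_threshold: float = 0.5,
) -> float:
    """AP over a set of images for one class.

    ``predictions`` are (image_id, box, confidence) triples;
    ``ground_truths`` maps image_id to its boxes.  The confidence sweep
    uses the greedy matcher; AP integrates the all-point precision
    envelope over recall.  With no ground-truth boxes AP is defined as 0.
    """
    n_gt = sum(len(v) for v in ground_truths.values())
    if n_gt == 0:
        return 0.0
    if not predictions:
        return 0.0
    order = sorted(range(len(predictions)), key=lambda i: -predictions[i][2])
    matched: dict[str, set[int]] = {k: set() for k in ground_truths}
    tp_flags = np.zeros(len(order))
    for rank, i in enumerate(order):
        image_id, box, _conf = predictions[i]
        gts = ground_truths.get(image_id, [])
        taken = matched.setdefault(image_id, set())
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(gts):
            if j in taken:
                continue
            iou = box_iou(box, gt)
            if iou >= iou_threshold and iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0:
            taken.add(best_j)
            tp_flags[rank] = 1.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(1.0 - tp_flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # all-point interpolation: running maximum of precision from the right
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, envelope):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def mean_average_precision(
    predictions_by_class: dict[int, list[tuple[str, Box, float]]],
    ground_truths_by_class: dict[int, dict[str, list[Box]]],
    iou_threshold: float = 0.5,
) -> tuple[float, dict[int, float]]:
    """mAP = mean over the class universe of per-class AP."""
    universe = set(ground_truths_by_class)
    unknown = set(predictions_by_class) - universe
    if unknown:
        raise ValueError(f"predictions contain classes outside the universe: {unknown}")
    ap_per_class = {
        cls: average_precision(
            predictions_by_class.get(cls, []), ground_truths_by_class[cls], iou_threshold
        )
        for cls in sorted(universe)
    }
    if not ap_per_class:
        return 0.0, {}
    return float(np.mean(list(ap_per_class.values()))), ap_per_class


@dataclass
class CountScores:
    R2: float
    RMSE: float
    RRMSE_pct: float
    n: int


def count_metrics(y_true, y_pred) -> CountScores:
    """Count-regression scores comparing predicted with true per-image counts."""
    y = np.asarray(y_true, dtype=np.float64)
    x = np.asarray(y_pred, dtype=np.float64)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D sequences")
    if y.size < 2:
        raise ValueError("need at least two images for count metrics")
    sse = float(((y - x) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("all true counts are equal: R² is undefined")
    rmse = float(np.sqrt(sse / y.size))
    return CountScores(
        R2=1.0 - sse / sst,
        RMSE=rmse,
        RRMSE_pct=100.0 * rmse / float(y.mean()),
        n=int(y.size),
    )


def yolo_to_pixel_box(box: tuple, width: int, height: int) -> Box:
    """(class, xc, yc, w, h[, conf]) normalized → pixel (x1, y1, x2, y2)."""
    _cls, xc, yc, w, h = box[:5]
    return (
        (xc - w / 2) * width,
        (yc - h / 2) * height,
        (xc + w / 2) * width,
        (yc + h / 2) * height,
    )


def score_prediction_files(
    pred_paths: list[str | Path],
    gt_paths: list[str | Path],
    image_sizes: list[tuple[int, int]],
    iou_threshold: float = 0.5,
) -> pd.DataFrame:
    """Score YOLO-format prediction files against label files, per image.

    Prediction files carry a sixth confidence column.  Returns one row per
    image with TP/FP/FN, P/R/F1 and the counts, plus a trailing row with
    the pooled metrics and the single-class AP across all images.
    """
    rows = []
    all_preds: list[tuple[str, Box, float]] = []
    all_gts: dict[str, list[Box]] = {}
    tot_tp = tot_fp = tot_fn = 0
    for pred_path, gt_path, (h, w) in zip(pred_paths, gt_paths, image_sizes):
        image_id = str(gt_path)
        preds = dataset_io.read_yolo_labels(pred_path, with_confidence=True)
        gts = dataset_io.read_yolo_labels(gt_path)
        pred_boxes = [yolo_to_pixel_box(p, w, h) for p in preds]
        confs = [p[5] for p in preds]
        gt_boxes = [yolo_to_pixel_box(g, w, h) for g in gts]
        all_gts[image_id] = gt_boxes
        all_preds.extend(
            (image_id, b, c) for b, c in zip(pred_boxes, confs)
        )
        match = match_detections(pred_boxes, gt_boxes, confs, iou_threshold)
        p, r, f1 = detection_metrics(match)
        tot_tp += match.TP
        tot_fp += match.FP
        tot_fn += match.FN
        rows.append(
            {
                "image": image_id,
                "TP": match.TP,
                "FP": match.FP,
                "FN": match.FN,
                "P": p,
                "R": r,
                "F1": f1,
                "true_count": len(gt_boxes),
                "pred_count": len(pred_boxes),
            }
        )
    pooled = MatchResult(TP=tot_tp, FP=tot_fp, FN=tot_fn, pairs=[])
    p, r, f1 = detection_metrics(pooled)
    rows.append(
        {
            "image": "__pooled__",
            "TP": tot_tp,
            "FP": tot_fp,
            "FN": tot_fn,
            "P": p,
            "R": r,
            "F1": f1,
            "true_count": sum(len(v) for v in all_gts.values()),
            "pred_count": len(all_preds),
            "AP50": average_precision(all_preds, all_gts, iou_threshold),
        }
    )
    return pd.DataFrame(rows)
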