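"""End-to-end altitude experiment: generate, segment, train, count, score.

Mirrors the study design: a synthetic dataset per flight altitude (15/30/45
m by default), a 2:1 train/validation split per altitude, a color-index
separability analysis on training imagery, and two counting methods scored
on the validation images of each altitude:

* ``otsu``  — unsupervised: the working index (EXG by default) thresholded
  per image by maximum inter-class variance, then morphological cleanup and
  connected-component counting;
* ``svm``   — supervised: the pixel SVM trained on patches from a few
  training images of the same altitude, then the same cleanup/counting.

The minimum component area, opening radius and sampling patch size all
shrink with altitude along with the seedlings themselves.  Results are a
tidy table (method × altitude × P/R/mAP@0.5/F1/R²/RMSE/RRMSE) plus the
per-image true-vs-predicted counts behind the R² values.  Everything is a
deterministic function of the experiment seed.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import svm_counter
from .color_index import compute_all_indices
from .dataset_io import ExperimentConfig, read_yolo_labels
from .evaluation import (
    MatchResult,
    average_precision,
    count_metrics,
    detection_metrics,
    match_detections,
    yolo_to_pixel_box,
)
from .otsu import SeparabilityReport, segment, separability_analysis
from .synthetic_field import SceneSpec, generate_dataset, generate_scene

log = logging.getLogger("seedstand")


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def patches_from_truth(
    image: np.ndarray,
    gt_boxes_px: list[tuple[float, float, float, float]],
    patch_size: int,
    n_per_class: int,
    rng: np.random.Generator,
    purity_mask: np.ndarray | None = None,
    candidates_per_patch: int = 12,
    max_attempts: int = 2000,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Top-left corners of plant patches (inside boxes) and soil patches
    (clear of all boxes) for the separability analysis.

    A bounding box of a rosette contains soil between the leaves, whereas
    the patches the analysis is meant to emulate are visually chosen pure
    plant samples.  When ``purity_mask`` (a known vegetation mask) is
    given, each plant patch is the purest of ``candidates_per_patch``
    random in-box positions.
    """
    h, w = image.shape[:2]
    big = [b for b in gt_boxes_px if b[2] - b[0] >= patch_size and b[3] - b[1] >= patch_size]
    if not big:
        raise ValueError(f"no box can hold a {patch_size}px patch")
    fg = []
    for _ in range(n_per_class):
        best, best_purity = None, -1.0
        for _cand in range(candidates_per_patch if purity_mask is not None else 1):
            x1, y1, x2, y2 = big[rng.integers(len(big))]
            r = int(np.clip(rng.uniform(y1, y2 - patch_size), 0, h - patch_size))
            c = int(np.clip(rng.uniform(x1, x2 - patch_size), 0, w - patch_size))
            if purity_mask is None:
                purity = 0.0
            else:
                purity = float(purity_mask[r : r + patch_size, c : c + patch_size].mean())
            if purity > best_purity:
                best, best_purity = (r, c), purity
        fg.append(best)
    bg: list[tuple[int, int]] = []
    attempts = 0
    while len(bg) < n_per_class and attempts < max_attempts:
        attempts += 1
        r = int(rng.integers(0, h - patch_size + 1))
        c = int(rng.integers(0, w - patch_size + 1))
        clear = all(
            not (c < x2 and c + patch_size > x1 and r < y2 and r + patch_size > y1)
            for x1, y1, x2, y2 in gt_boxes_px
        )
        if clear:
            bg.append((r, c))
    if not bg:
        raise ValueError("could not find soil patches clear of all boxes")
    return fg, bg


def _load_gt(row) -> list[tuple[float, float, float, float]]:
    boxes = read_yolo_labels(row["label"])
    return [yolo_to_pixel_box(b, int(row["width_px"]), int(row["height_px"])) for b in boxes]


def _count_image(
    image: np.ndarray,
    mask: np.ndarray,
    min_area: float,
    opening_radius: int,
) -> tuple[int, list]:
    return svm_counter.count_components(mask, min_area_px=min_area, opening_radius=opening_radius)


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full multi-altitude counting experiment.

    Returns a dict with the results table, the per-image counts table, the
    separability report, and the manifest; the same tables are written as
    CSV under ``config.out_dir``.  Fails fast with the stage name logged on
    any stage error.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)

    stage = "generate-dataset"
    try:
        t0 = _stage(stage)
        template = SceneSpec(rng_seed=config.rng_seed, **config.scene)
        manifest = generate_dataset(
            template,
            n_images_per_altitude=config.images_per_altitude,
            altitudes=tuple(config.altitudes),
            out_dir=out_dir / "dataset",
            count_jitter=config.count_jitter,
            split_ratio=config.split_ratio,
        )
        log.info("generated %d images in %.1fs", len(manifest), time.perf_counter() - t0)

        stage = "separability"
        t0 = _stage(stage)
        ref_alt = min(config.altitudes)
        ref_rows = manifest[(manifest["altitude_m"] == ref_alt) & (manifest["split"] == "train")]
        ref_row = ref_rows.iloc[0]
        ref_image = iio.imread(ref_row["image"])
        # re-render the reference scene to recover its exact vegetation
        # mask, used only to pick pure plant patches (as a human would)
        from dataclasses import replace as _replace

        ref_spec = _replace(
            template,
            altitude_m=float(ref_row["altitude_m"]),
            image_size=(int(ref_row["height_px"]), int(ref_row["width_px"])),
            n_seedlings=int(ref_row["count"]),
            rng_seed=int(ref_row["scene_seed"]),
            gsd_cm_per_px=None,
        )
        _img_check, _gt_check, ref_mask = generate_scene(ref_spec, return_mask=True)
        fg, bg = patches_from_truth(
            ref_image,
            _load_gt(ref_row),
            config.base_patch_size_px,
            n_per_class=max(8, config.patches_per_class),
            rng=rng,
            purity_mask=ref_mask,
        )
        report: SeparabilityReport = separability_analysis(
            ref_image, fg, bg, patch_size=config.base_patch_size_px
        )
        report.to_frame().to_csv(out_dir / "separability.csv", index=False)
        log.info(
            "separability ranking: %s (%.1fs)",
            ", ".join(r.index_name for r in report.records),
            time.perf_counter() - t0,
        )

        results_rows = []
        count_rows = []
        for alt in config.altitudes:
            stage = f"altitude-{alt}"
            t0 = _stage(stage)
            alt_rows = manifest[manifest["altitude_m"] == alt]
            train_rows = alt_rows[alt_rows["split"] == "train"]
            val_rows = alt_rows[alt_rows["split"] == "val"]
            patch_size = svm_counter.patch_size_for_altitude(config.base_patch_size_px, alt)
            min_area = svm_counter.min_area_for_altitude(config.base_min_area_px, alt)
            radius = svm_counter.opening_radius_for_altitude(config.base_opening_radius, alt)

            # train the pixel SVM on a few training images of this altitude
            sample_sets = []
            for _, row in train_rows.head(config.n_train_images_for_svm).iterrows():
                image = iio.imread(row["image"])
                boxes = read_yolo_labels(row["label"])
                from .synthetic_field import GroundTruth

                truth = GroundTruth(boxes=boxes)
                sample_sets.append(
                    svm_counter.build_samples(
                        image,
                        truth,
                        n_patches=config.patches_per_class,
                        patch_size=patch_size,
                        rng_seed=int(rng.integers(2**31)),
                        index_names=(config.index_name,),
                    )
                )
            model = svm_counter.train_pixel_svm(
                svm_counter.merge_samples(sample_sets),
                kernel=config.svm_kernel,
                C=config.svm_C,
                index_names=(config.index_name,),
            )

            per_method_counts: dict[str, list[int]] = {"otsu": [], "svm": []}
            truths: list[int] = []
            match_totals = {m: [0, 0, 0] for m in per_method_counts}
            ap_preds: dict[str, list] = {m: [] for m in per_method_counts}
            ap_gts: dict[str, dict] = {m: {} for m in per_method_counts}
            for _, row in val_rows.iterrows():
                image = iio.imread(row["image"])
                gt_boxes = _load_gt(row)
                truths.append(int(row["count"]))
                indices = compute_all_indices(image)
                masks = {
                    "otsu": segment(indices[config.index_name]),
                    "svm": svm_counter.classify_pixels(model, image),
                }
                for method, mask in masks.items():
                    count, dets = _count_image(image, mask, min_area, radius)
                    per_method_counts[method].append(count)
                    pred_boxes = [d.bbox for d in dets]
                    confs = [d.confidence for d in dets]
                    match = match_detections(pred_boxes, gt_boxes, confs)
                    match_totals[method][0] += match.TP
                    match_totals[method][1] += match.FP
                    match_totals[method][2] += match.FN
                    image_id = str(row["image"])
                    ap_gts[method][image_id] = gt_boxes
                    ap_preds[method].extend(
                        (image_id, b, c) for b, c in zip(pred_boxes, confs)
                    )
                    count_rows.append(
                        {
                            "altitude_m": alt,
                            "method": method,
                            "image": str(row["image"]),
                            "true_count": int(row["count"]),
                            "pred_count": count,
                        }
                    )
            for method in per_method_counts:
                scores = count_metrics(truths, per_method_counts[method])
                tp, fp, fn = match_totals[method]
                p, r, f1 = detection_metrics(MatchResult(TP=tp, FP=fp, FN=fn, pairs=[]))
                ap = average_precision(ap_preds[method], ap_gts[method])
                results_rows.append(
                    {
                        "method": method,
                        "altitude_m": alt,
                        "P": p,
                        "R": r,
                        "mAP50": ap,  # single-class: mAP == AP
                        "F1": f1,
                        "R2": scores.R2,
                        "RMSE": scores.RMSE,
                        "RRMSE_pct": scores.RRMSE_pct,
                        "n_val": scores.n,
                    }
                )
            log.info("altitude %s done in %.1fs", alt, time.perf_counter() - t0)

        stage = "write-results"
        results = pd.DataFrame(results_rows)
        counts = pd.DataFrame(count_rows)
        results.to_csv(out_dir / "results.csv", index=False)
        counts.to_csv(out_dir / "counts.csv", index=False)
        if config.make_plots:
            _plot(results, counts, out_dir)
    except Exception:
        log.error("experiment failed during stage %r", stage)
        raise

    return {
        "results": results,
        "counts": counts,
        "separability": report,
        "manifest": manifest,
    }


def _plot(results: pd.DataFrame, counts: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    altitudes = sorted(counts["altitude_m"].unique())
    methods = sorted(counts["method"].unique())
    fig, axes = plt.subplots(
        len(methods), len(altitudes), figsize=(4 * len(altitudes), 4 * len(methods)), squeeze=False
    )
    for i, method in enumerate(methods):
        for j, alt in enumerate(altitudes):
            sub = counts[(counts["method"] == method) & (counts["altitude_m"] == alt)]
            ax = axes[i][j]
            ax.scatter(sub["true_count"], sub["pred_count"], s=18)
            lim = [0, max(sub["true_count"].max(), sub["pred_count"].max()) * 1.1]
            ax.plot(lim, lim, "k--", lw=1)
            r2 = results[
                (results["method"] == method) & (results["altitude_m"] == alt)
            ]["R2"].iloc[0]
            ax.set_title(f"{method} @ {alt:g} m  (R²={r2:.2f})")
            ax.set_xlabel("true count")
            ax.set_ylabel("predicted count")
    fig.tight_layout()
    fig.savefig(out_dir / "count_scatter.png", dpi=110)
    plt.close(fig)
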