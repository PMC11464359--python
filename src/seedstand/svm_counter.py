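"""Seedling counting by supervised pixel classification.

The counting path is: sample labeled pixel patches (plant pixels inside
ground-truth boxes, soil pixels outside all boxes), train a maximum-margin
support vector machine on per-pixel color features (chromatic r, g, b plus
configured vegetation-index values), classify every pixel of a new image,
clean the binary map with a morphological opening, and count 8-connected
components above a minimum area as individual seedlings.  Each component
becomes a detection with a bounding box and a confidence proportional to
its area relative to the median component, so precision/recall/AP are
computable for this detector as well.

Because a seedling's pixel footprint shrinks with the square of flight
altitude, the minimum component area (and the opening radius) must shrink
the same way; :func:`min_area_for_altitude` and
:func:`opening_radius_for_altitude` apply that quadratic (resp. linear)
scaling from their 15 m base values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .color_index import compute_index, to_chromatic

SORGHUM, SOIL = 1, 0


@dataclass
class PixelSampleSet:
    """Labeled per-pixel feature rows sampled from annotated imagery."""

    features: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) values in {SORGHUM, SOIL}
    feature_names: tuple[str, ...]
    provenance: list[tuple[str, int, int]] = field(default_factory=list)  # (class, row, col)


@dataclass
class PixelModel:
    pipeline: Pipeline
    feature_names: tuple[str, ...]
    index_names: tuple[str, ...]
    kernel: str


def pixel_features(
    image: np.ndarray, index_names: tuple[str, ...] = ("EXG",)
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Per-pixel feature stack: chromatic shares plus index values, (H, W, d)."""
    chrom = to_chromatic(image)
    layers = [chrom.r, chrom.g, chrom.b]
    names = ["r", "g", "b"]
    for name in index_names:
        layers.append(compute_index(chrom, name, original=image).values)
        names.append(name)
    return np.stack(layers, axis=-1), tuple(names)


def build_samples(
    image: np.ndarray,
    truth,
    n_patches: int = 8,
    patch_size: int = 20,
    rng_seed: int = 0,
    index_names: tuple[str, ...] = ("EXG",),
    refine_labels: str | None = "otsu",
    max_attempts: int = 2000,
) -> PixelSampleSet:
    """Sample plant and soil pixel patches from one annotated image.

    ``n_patches`` square patches per class: plant patches lie fully inside
    a ground-truth box, soil patches intersect no box.  A bounding box of a
    multi-leaf rosette contains plenty of soil between the leaves, so with
    ``refine_labels="otsu"`` (the default) the per-pixel labels inside
    plant patches are refined by thresholding the excess-green values of
    the pooled patch pixels at their maximum inter-class variance — the
    segmentation stage feeding the recognition stage.  The pooled patch
    pixels are roughly half plant, which is the bimodal regime where that
    threshold is reliable even when plants cover only a small fraction of
    the whole frame.  With ``refine_labels=None`` every pixel of a plant
    patch is labeled plant (weak box-level supervision).  Raises when
    either class yields no patch (e.g. a plant-free scene, or boxes
    smaller than the patch).
    """
    if refine_labels not in (None, "otsu"):
        raise ValueError(f"unknown refine_labels mode {refine_labels!r}")
    rng = np.random.default_rng(rng_seed)
    h, w = image.shape[:2]
    feats, names = pixel_features(image, index_names)
    boxes_px = truth.to_pixel_boxes(w, h)
    big_enough = [
        (x1, y1, x2, y2)
        for x1, y1, x2, y2 in boxes_px
        if x2 - x1 >= patch_size and y2 - y1 >= patch_size
    ]
    if not big_enough:
        raise ValueError(
            f"no ground-truth box can hold a {patch_size}×{patch_size} plant patch"
        )

    def overlaps_any(r: int, c: int) -> bool:
        for x1, y1, x2, y2 in boxes_px:
            if c < x2 and c + patch_size > x1 and r < y2 and r + patch_size > y1:
                return True
        return False

    exg = compute_index(to_chromatic(image), "EXG").values

    fg_rows, fg_exg, fg_provenance = [], [], []
    for _ in range(n_patches):
        x1, y1, x2, y2 = big_enough[rng.integers(len(big_enough))]
        r = int(rng.uniform(max(0, y1), min(h, y2) - patch_size))
        c = int(rng.uniform(max(0, x1), min(w, x2) - patch_size))
        r = int(np.clip(r, 0, h - patch_size))
        c = int(np.clip(c, 0, w - patch_size))
        fg_rows.append(feats[r : r + patch_size, c : c + patch_size].reshape(-1, feats.shape[-1]))
        fg_exg.append(exg[r : r + patch_size, c : c + patch_size].ravel())
        fg_provenance.append(("sorghum", r, c))

    bg_rows, bg_exg, bg_provenance = [], [], []
    attempts = 0
    while len(bg_rows) < n_patches and attempts < max_attempts:
        attempts += 1
        r = int(rng.integers(0, h - patch_size + 1))
        c = int(rng.integers(0, w - patch_size + 1))
        if overlaps_any(r, c):
            continue
        bg_rows.append(feats[r : r + patch_size, c : c + patch_size].reshape(-1, feats.shape[-1]))
        bg_exg.append(exg[r : r + patch_size, c : c + patch_size].ravel())
        bg_provenance.append(("soil", r, c))
    if not bg_rows:
        raise ValueError("could not sample any soil patch clear of ground-truth boxes")

    if refine_labels == "otsu":
        from .otsu import otsu_threshold, quantize

        pooled = np.concatenate(fg_exg + bg_exg)
        gray = quantize(pooled)
        result = otsu_threshold(gray)
        lo, hi = gray.mapping
        if gray.constant or result.degenerate:
            fg_labels = [np.full(p.size, SORGHUM) for p in fg_exg]
        else:
            cut = lo + result.T * (hi - lo) / 255.0
            fg_labels = [np.where(p > cut, SORGHUM, SOIL) for p in fg_exg]
    else:
        fg_labels = [np.full(p.size, SORGHUM) for p in fg_exg]

    features = np.vstack(fg_rows + bg_rows)
    labels = np.concatenate(
        fg_labels + [np.full(len(bg_rows) * patch_size * patch_size, SOIL)]
    )
    return PixelSampleSet(
        features=features,
        labels=labels,
        feature_names=names,
        provenance=fg_provenance + bg_provenance,
    )


def merge_samples(sample_sets: list[PixelSampleSet]) -> PixelSampleSet:
    names = sample_sets[0].feature_names
    if any(s.feature_names != names for s in sample_sets):
        raise ValueError("sample sets have inconsistent feature configurations")
    return PixelSampleSet(
        features=np.vstack([s.features for s in sample_sets]),
        labels=np.concatenate([s.labels for s in sample_sets]),
        feature_names=names,
        provenance=[p for s in sample_sets for p in s.provenance],
    )


def train_pixel_svm(
    samples: PixelSampleSet,
    kernel: str = "linear",
    C: float = 1.0,
    index_names: tuple[str, ...] = ("EXG",),
) -> PixelModel:
    """Fit a maximum-margin pixel classifier on standardized features."""
    classes = np.unique(samples.labels)
    if classes.size < 2:
        raise ValueError("training requires both plant and soil samples")
    pipeline = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=kernel, C=C)),
        ]
    )
    pipeline.fit(samples.features, samples.labels)
    return PixelModel(
        pipeline=pipeline,
        feature_names=samples.feature_names,
        index_names=index_names,
        kernel=kernel,
    )


def classify_pixels(model: PixelModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel plant/soil map for a whole image (True = plant).

    For the linear kernel the decision function is evaluated directly from
    the primal weights, which is orders of magnitude faster than support-
    vector expansion over hundreds of thousands of pixels.
    """
    feats, names = pixel_features(image, model.index_names)
    if names != model.feature_names:
        raise ValueError(
            f"feature mismatch: model expects {model.feature_names}, image yields {names}"
        )
    flat = feats.reshape(-1, feats.shape[-1])
    scaler: StandardScaler = model.pipeline.named_steps["scale"]
    svm: SVC = model.pipeline.named_steps["svm"]
    scaled = scaler.transform(flat)
    if model.kernel == "linear":
        decision = scaled @ svm.coef_.ravel() + svm.intercept_[0]
        positive = svm.classes_[1]
        pred = np.where(decision > 0, positive, svm.classes_[0])
    else:
        pred = svm.predict(scaled)
    return (pred == SORGHUM).reshape(image.shape[:2])


@dataclass
class ComponentDetection:
    """One connected component proposed as a seedling."""

    bbox: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max), half-open
    area_px: int
    confidence: float


def count_components(
    mask: np.ndarray,
    min_area_px: float = 25.0,
    opening_radius: int = 0,
) -> tuple[int, list[ComponentDetection]]:
    """Count seedlings as cleaned 8-connected foreground components.

    A morphological opening (square structuring element of side
    ``2*opening_radius + 1``; radius 0 is a no-op) removes thin bridges and
    speckle, then components with area below ``min_area_px`` are dropped.
    Confidence is ``min(1, area / median_area)`` over the kept components.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise TypeError("count_components expects a boolean mask")
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    if opening_radius > 0:
        structure = np.ones((2 * opening_radius + 1, 2 * opening_radius + 1), dtype=bool)
        mask = ndimage.binary_opening(mask, structure=structure)
    labeled = label(mask, connectivity=2)
    regions = [r for r in regionprops(labeled) if r.area >= min_area_px]
    if not regions:
        return 0, []
    median_area = float(np.median([r.area for r in regions]))
    detections = []
    for r in regions:
        y1, x1, y2, x2 = r.bbox
        conf = min(1.0, float(r.area) / median_area) if median_area > 0 else 1.0
        detections.append(
            ComponentDetection(
                bbox=(int(x1), int(y1), int(x2), int(y2)),
                area_px=int(r.area),
                confidence=max(conf, 1e-6),
            )
        )
    return len(detections), detections


def min_area_for_altitude(
    base_min_area: float,
    altitude_m: float,
    reference_altitude_m: float = 15.0,
    floor_px: float = 4.0,
) -> float:
    """Scale the area gate quadratically with GSD (area ∝ 1/altitude²).

    The gate never drops below ``floor_px``: a component of only a few
    pixels is indistinguishable from sensor noise at any ground sample
    distance.
    """
    return max(floor_px, base_min_area * (reference_altitude_m / altitude_m) ** 2)


def opening_radius_for_altitude(
    base_radius: int, altitude_m: float, reference_altitude_m: float = 15.0
) -> int:
    """Scale the opening radius linearly with GSD (length ∝ 1/altitude)."""
    return int(round(base_radius * reference_altitude_m / altitude_m))


def patch_size_for_altitude(
    base_patch_px: int, altitude_m: float, reference_altitude_m: float = 15.0
) -> int:
    """Scale the sampling patch side linearly with GSD, floored at 4 px."""
    return max(4, int(round(base_patch_px * reference_altitude_m / altitude_m)))
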