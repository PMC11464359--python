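"""Label files, annotation conversion, dataset splitting and configuration.

The interchange format throughout is the YOLO TXT convention: one line per
object, ``class x_center y_center width height``, all coordinates
normalized by image size.  Prediction files may carry a sixth confidence
column.  Floats are written with Python's shortest round-tripping
representation, so a label file parses back to the in-memory boxes exactly.

Rectangle annotations exported by interactive labeling tools (a JSON
document whose ``shapes`` each hold a string ``label`` and two corner
``points``) are converted to the same TXT convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

DEFAULT_CLASS_MAP = {"sorghum": 0}


@dataclass
class AnnotationRecord:
    """One image's rectangle annotations in pixel coordinates."""

    image_path: str
    image_size: tuple[int, int]  # (height, width)
    shapes: list[tuple[tuple[float, float], tuple[float, float], str]]


def load_annotation_json(path: str | Path) -> AnnotationRecord:
    """Read a rectangle-annotation JSON document.

    Accepts either a mapping with ``shapes`` / ``imageHeight`` /
    ``imageWidth`` keys (the dialect written by common labeling tools) or a
    bare list of shapes with the size supplied later; unknown fields are
    ignored.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, list):
        shapes_raw = doc
        size = (0, 0)
        image_path = str(path)
    else:
        shapes_raw = doc.get("shapes", [])
        size = (int(doc.get("imageHeight", 0)), int(doc.get("imageWidth", 0)))
        image_path = doc.get("imagePath", str(path))
    shapes = []
    for s in shapes_raw:
        pts = s["points"]
        if len(pts) != 2:
            raise ValueError(f"expected two corner points per rectangle, got {len(pts)}")
        (x1, y1), (x2, y2) = pts
        shapes.append(((float(x1), float(y1)), (float(x2), float(y2)), str(s.get("label", "sorghum"))))
    return AnnotationRecord(image_path=image_path, image_size=size, shapes=shapes)


def convert_annotation_json_to_yolo(
    record: AnnotationRecord,
    class_map: dict[str, int] | None = None,
) -> list[str]:
    """Convert rectangle annotations to normalized YOLO label lines.

    Corner order is normalized (either diagonal is accepted); zero-area
    rectangles and a missing image size raise ValueError.
    """
    class_map = class_map or DEFAULT_CLASS_MAP
    h, w = record.image_size
    if h <= 0 or w <= 0:
        raise ValueError("image size must be known to normalize annotations")
    lines = []
    for (x1, y1), (x2, y2), label in record.shapes:
        xmin, xmax = sorted((x1, x2))
        ymin, ymax = sorted((y1, y2))
        if xmax - xmin <= 0 or ymax - ymin <= 0:
            raise ValueError(f"zero-area rectangle ({x1},{y1})-({x2},{y2})")
        cls = class_map.get(label)
        if cls is None:
            raise ValueError(f"label {label!r} not in class map {class_map}")
        xc = (xmin + xmax) / 2 / w
        yc = (ymin + ymax) / 2 / h
        bw = (xmax - xmin) / w
        bh = (ymax - ymin) / h
        lines.append(format_yolo_line((cls, xc, yc, bw, bh)))
    return lines


def format_yolo_line(box: tuple) -> str:
    cls = int(box[0])
    rest = " ".join(repr(float(v)) for v in box[1:])
    return f"{cls} {rest}"


def write_yolo_labels(path: str | Path, boxes: list[tuple]) -> None:
    """Write boxes (class, xc, yc, w, h[, confidence]) to a YOLO TXT file."""
    with open(path, "w") as fh:
        for box in boxes:
            fh.write(format_yolo_line(box) + "\n")


def read_yolo_labels(
    path: str | Path, with_confidence: bool = False
) -> list[tuple]:
    """Parse a YOLO TXT file back to (class, xc, yc, w, h[, conf]) tuples."""
    boxes = []
    expected = 6 if with_confidence else 5
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != expected:
                raise ValueError(
                    f"{path}: expected {expected} fields per line, got {len(parts)}"
                )
            boxes.append((int(parts[0]), *(float(p) for p in parts[1:])))
    return boxes


def parse_ratio(ratio: str) -> tuple[int, int]:
    try:
        a, b = ratio.split(":")
        a, b = int(a), int(b)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"unparseable split ratio {ratio!r}; expected 'a:b'") from exc
    if a <= 0 or b <= 0:
        raise ValueError(f"split ratio parts must be positive, got {ratio!r}")
    return a, b


def split_dataset(
    manifest: pd.DataFrame,
    ratio: str = "2:1",
    stratify_by: str | None = "altitude_m",
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Assign a train/val split column, stratified and seeded.

    Within each stratum the images are shuffled and the first
    ``ceil(n * a / (a + b))`` go to train, the remainder to validation —
    so 36 images at 2:1 give exactly 24/12, and a single image goes to
    train with a warning about the empty validation side.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    a, b = parse_ratio(ratio)
    rng = np.random.default_rng(rng_seed)
    manifest = manifest.copy()
    manifest["split"] = ""
    groups = (
        [(None, manifest.index)]
        if stratify_by is None
        else [(k, g.index) for k, g in manifest.groupby(stratify_by, sort=True)]
    )
    for key, idx in groups:
        idx = np.asarray(idx)
        order = rng.permutation(len(idx))
        n_train = ceil(len(idx) * a / (a + b))
        train_idx = idx[order[:n_train]]
        val_idx = idx[order[n_train:]]
        manifest.loc[train_idx, "split"] = "train"
        manifest.loc[val_idx, "split"] = "val"
        if len(val_idx) == 0:
            warnings.warn(
                f"stratum {key!r} has {len(idx)} image(s): validation split is empty",
                stacklevel=2,
            )
    return manifest


@dataclass
class ExperimentConfig:
    """Parameters of a full multi-altitude counting experiment."""

    altitudes: tuple[float, ...] = (15.0, 30.0, 45.0)
    images_per_altitude: int = 36
    split_ratio: str = "2:1"
    index_name: str = "EXG"
    svm_kernel: str = "linear"
    svm_C: float = 1.0
    n_train_images_for_svm: int = 3
    patches_per_class: int = 8
    base_patch_size_px: int = 20
    base_min_area_px: float = 25.0
    base_opening_radius: int = 0
    count_jitter: float = 0.4
    rng_seed: int = 0
    out_dir: str = "results/experiment"
    make_plots: bool = False
    scene: dict = field(default_factory=dict)  # overrides for SceneSpec fields

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "altitudes" in doc:
            doc["altitudes"] = tuple(doc["altitudes"])
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
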