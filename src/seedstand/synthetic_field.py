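"""Synthetic nadir UAV imagery of row-planted seedlings with exact ground truth.

Generates field scenes that emulate what a drone sees looking straight down
at a young row crop: green multi-leaf seedlings arranged in rows (0.6 m row
spacing by default) over textured brown soil, with neighbor overlap,
illumination gradients, sensor noise, and unlabeled weeds as false-positive
pressure.  Every scene comes with one ground-truth bounding box per
seedling, so detection and counting can be scored exactly without any real
imagery.

Scale is controlled by the flight altitude through the ground sample
distance (GSD): 0.5 cm/px at the 15 m reference altitude, linear in
altitude.  All physical dimensions (leaf lengths, plant spacing, soil
texture correlation lengths) are specified in centimetres and converted to
pixels through the GSD, so a seedling's pixel footprint shrinks with the
square of altitude exactly as projective geometry dictates.

Generation is a pure function of the scene spec (including its seed):
identical specs produce bit-identical images and boxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, ellipse
from skimage.transform import downscale_local_mean

from . import dataset_io

REFERENCE_ALTITUDE_M = 15.0
GSD_AT_REFERENCE_CM = 0.5  # cm per pixel at the reference altitude

SOIL_BASE_RGB = np.array([125.0, 92.0, 62.0])
PLANT_BASE_RGB = np.array([55.0, 132.0, 50.0])
WEED_BASE_RGB = np.array([112.0, 138.0, 48.0])

# physical plant geometry, in cm
LEAF_LENGTH_CM = (4.0, 7.0)
LEAF_ASPECT = (0.16, 0.24)  # half-width as a fraction of full length
CORE_RADIUS_CM = 1.2
IN_ROW_SPACING_CM = (22.0, 32.0)  # ~27 cm mean, typical transplant density
TOUCHING_SPACING_CM = (6.0, 10.0)
ROW_MARGIN_CM = 8.0
WEED_LEAF_CM = (2.0, 3.5)


def gsd_for_altitude(altitude_m: float) -> float:
    """Ground sample distance (cm/px), linear in altitude."""
    return GSD_AT_REFERENCE_CM * altitude_m / REFERENCE_ALTITUDE_M


@dataclass
class SceneSpec:
    """Generative parameters of one synthetic field image.

    ``gsd_cm_per_px`` is derived from altitude when left as None.
    ``overlap_fraction`` is the fraction of seedlings deliberately placed
    touching their in-row neighbor, producing the merged-mask failure mode
    that makes counting hard.  ``plants_per_box`` renders that many shoots
    per planting position under a single annotation box (hill-drop sowing);
    the default annotates one seedling per box.
    """

    altitude_m: float = 15.0
    image_size: tuple[int, int] = (600, 960)  # (height_px, width_px): 3.0 m × 4.8 m at 15 m

    n_seedlings: int = 60
    row_spacing_m: float = 0.6
    overlap_fraction: float = 0.08
    illumination_gradient: float = 0.15
    noise_sd: float = 6.0
    psf_sigma_px: float = 0.7  # optical/resampling blur, fixed in pixels
    plant_scale_range: tuple[float, float] = (0.55, 1.25)  # emergence variability
    weed_density: float = 0.05  # weeds per m²
    plants_per_box: int = 1
    rng_seed: int = 0
    gsd_cm_per_px: float | None = None

    def __post_init__(self) -> None:
        if self.gsd_cm_per_px is None:
            self.gsd_cm_per_px = gsd_for_altitude(self.altitude_m)
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError(f"image size must be positive, got {self.image_size}")
        if self.n_seedlings < 0:
            raise ValueError("n_seedlings must be non-negative")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Normalized bounding boxes, one per seedling (YOLO semantics)."""

    boxes: list[tuple[int, float, float, float, float]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.boxes)

    def to_pixel_boxes(self, width: int, height: int) -> list[tuple[float, float, float, float]]:
        """Boxes as (x_min, y_min, x_max, y_max) in pixel coordinates."""
        out = []
        for _cls, xc, yc, w, h in self.boxes:
            out.append(
                (
                    (xc - w / 2) * width,
                    (yc - h / 2) * height,
                    (xc + w / 2) * width,
                    (yc + h / 2) * height,
                )
            )
        return out


def _smooth_field(shape: tuple[int, int], sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=sigma_px)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _render_soil(shape: tuple[int, int], px_per_cm: float, rng: np.random.Generator) -> np.ndarray:
    """Brown soil: low-frequency clod/brightness structure, a wet/dry field
    that trades red against blue (keeping the green share stable), and
    fine speckle."""
    clods = _smooth_field(shape, 12.0 * px_per_cm, rng)
    wetness = _smooth_field(shape, 30.0 * px_per_cm, rng)
    speckle = rng.standard_normal(shape)
    brightness = 1.0 + 0.18 * clods + 0.06 * speckle
    # wet/dry mottling trades red against blue by equal amounts, so the
    # channel sum — and with it the green share — stays untouched
    wet_dn = 15.0 * wetness
    img = np.empty(shape + (3,), dtype=np.float64)
    img[..., 0] = (SOIL_BASE_RGB[0] + wet_dn) * brightness
    img[..., 1] = SOIL_BASE_RGB[1] * brightness
    img[..., 2] = (SOIL_BASE_RGB[2] - wet_dn) * brightness
    return img


def _draw_plant(
    img: np.ndarray,
    mask: np.ndarray,
    cy: float,
    cx: float,
    px_per_cm: float,
    rng: np.random.Generator,
    base_rgb: np.ndarray,
    leaf_length_cm: tuple[float, float] = LEAF_LENGTH_CM,
    n_leaves_range: tuple[int, int] = (4, 7),
    core: bool = True,
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Render one multi-leaf rosette; returns the (rows, cols) it painted."""
    shape = mask.shape
    rows_acc: list[np.ndarray] = []
    cols_acc: list[np.ndarray] = []
    n_leaves = rng.integers(n_leaves_range[0], n_leaves_range[1] + 1)
    base_angle = rng.uniform(0, 2 * np.pi)
    plant_rgb = base_rgb + rng.normal(0, 9, size=3)
    for k in range(n_leaves):
        angle = base_angle + 2 * np.pi * k / n_leaves + rng.normal(0, 0.25)
        length_px = scale * rng.uniform(*leaf_length_cm) * px_per_cm
        half_len = length_px / 2
        half_wid = max(0.6, length_px * rng.uniform(*LEAF_ASPECT))
        # ellipse centered halfway along the leaf, long axis along `angle`
        ecy = cy + np.sin(angle) * half_len * 0.9
        ecx = cx + np.cos(angle) * half_len * 0.9
        rr, cc = ellipse(ecy, ecx, half_wid, half_len, rotation=-angle, shape=shape)
        if rr.size == 0:
            continue
        leaf_rgb = np.clip(plant_rgb + rng.normal(0, 5, size=3), 0, 255)
        # canopy self-shading: shaded leaves are darker and lit by bluish
        # skylight (blue share up, red share down, green share stable)
        shade = rng.uniform(0.0, 0.5)
        leaf_rgb = leaf_rgb * (1.0 - 0.7 * shade)
        leaf_rgb[0] *= 1.0 - 0.3 * shade
        leaf_rgb[2] *= 1.0 + 0.8 * shade
        img[rr, cc] = np.clip(leaf_rgb, 0, 255)
        mask[rr, cc] = True
        rows_acc.append(rr)
        cols_acc.append(cc)
    if core:
        rr, cc = disk((cy, cx), max(1.0, scale * CORE_RADIUS_CM * px_per_cm), shape=shape)
        if rr.size:
            img[rr, cc] = np.clip(plant_rgb * 0.85, 0, 255)
            mask[rr, cc] = True
            rows_acc.append(rr)
            cols_acc.append(cc)
    if not rows_acc:
        return None
    return np.concatenate(rows_acc), np.concatenate(cols_acc)


def _plan_positions(
    spec: SceneSpec,
    image_size: tuple[int, int],
    px_per_cm: float,
    rng: np.random.Generator,
) -> list[tuple[float, float, bool]]:
    """Plant centers (y_px, x_px, touches_neighbor), laid out in rows.

    Raises ValueError when the requested count cannot be placed within a
    bounded number of layout attempts.
    """
    h, w = image_size
    width_cm = w / px_per_cm
    row_pitch_px = spec.row_spacing_m * 100.0 * px_per_cm
    n_rows = max(1, int(h / row_pitch_px))
    row_offset = (h - (n_rows - 1) * row_pitch_px) / 2
    row_ys = [row_offset + k * row_pitch_px for k in range(n_rows)]
    n = spec.n_seedlings
    if n == 0:
        return []

    for _attempt in range(8):
        counts = np.zeros(n_rows, dtype=int)
        for i in range(n):
            counts[i % n_rows] += 1
        perm = rng.permutation(n_rows)
        counts = counts[perm]
        positions: list[tuple[float, float, bool]] = []
        feasible = True
        for row_y, k in zip(row_ys, counts):
            if k == 0:
                continue
            spacings = []
            touching = []
            for j in range(k):
                if j > 0 and rng.uniform() < spec.overlap_fraction:
                    spacings.append(rng.uniform(*TOUCHING_SPACING_CM))
                    touching.append(True)
                else:
                    spacings.append(rng.uniform(*IN_ROW_SPACING_CM) if j > 0 else 0.0)
                    touching.append(False)
            span = sum(spacings)
            slack = width_cm - 2 * ROW_MARGIN_CM - span
            if slack < 0:
                feasible = False
                break
            x_cm = ROW_MARGIN_CM + rng.uniform(0, slack)
            for j in range(k):
                x_cm += spacings[j]
                y_px = row_y + rng.normal(0, 2.0 * px_per_cm)
                positions.append((float(y_px), float(x_cm * px_per_cm), touching[j]))
        if feasible:
            return positions
    raise ValueError(
        f"cannot place {n} seedlings in a {image_size} image at "
        f"altitude {spec.altitude_m} m within the layout constraints"
    )


def generate_scene(
    spec: SceneSpec, return_mask: bool = False
) -> tuple[np.ndarray, GroundTruth] | tuple[np.ndarray, GroundTruth, np.ndarray]:
    """Render one synthetic field image and its ground truth.

    Returns the H×W×3 uint8 image and a :class:`GroundTruth` with one
    normalized box per seedling.  With ``return_mask=True`` the exact
    seedling pixel mask (weeds excluded) is returned as a third element.

    Scenes coarser than the reference GSD are rendered at the reference
    resolution and block-averaged down to the target pixel grid, so thin
    leaves dilute into mixed plant/soil pixels exactly as a real sensor
    integrates radiance over each pixel's ground footprint — the physical
    reason small seedlings become undetectable at high altitude.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_size
    # supersampling factor: render at or finer than the reference GSD
    ss = max(1, int(np.ceil(spec.gsd_cm_per_px / GSD_AT_REFERENCE_CM - 1e-9)))
    fh, fw = h * ss, w * ss
    px_per_cm = ss / spec.gsd_cm_per_px

    img = _render_soil((fh, fw), px_per_cm, rng)
    veg_mask = np.zeros((fh, fw), dtype=bool)

    # weeds first so seedlings paint over them
    area_m2 = (h * spec.gsd_cm_per_px / 100.0) * (w * spec.gsd_cm_per_px / 100.0)
    n_weeds = int(rng.poisson(spec.weed_density * area_m2))
    weed_mask = np.zeros((fh, fw), dtype=bool)
    for _ in range(n_weeds):
        wy = rng.uniform(0, fh)
        wx = rng.uniform(0, fw)
        _draw_plant(
            img,
            weed_mask,
            wy,
            wx,
            px_per_cm,
            rng,
            WEED_BASE_RGB,
            leaf_length_cm=WEED_LEAF_CM,
            n_leaves_range=(2, 3),
            core=False,
        )

    positions = _plan_positions(spec, (fh, fw), px_per_cm, rng)
    boxes: list[tuple[int, float, float, float, float]] = []
    for cy, cx, _touch in positions:
        rows_list: list[np.ndarray] = []
        cols_list: list[np.ndarray] = []
        plant_scale = rng.uniform(*spec.plant_scale_range)
        for shoot in range(spec.plants_per_box):
            oy = cy + (rng.normal(0, 2.0 * px_per_cm) if shoot > 0 else 0.0)
            ox = cx + (rng.normal(0, 2.0 * px_per_cm) if shoot > 0 else 0.0)
            painted = _draw_plant(
                img, veg_mask, oy, ox, px_per_cm, rng, PLANT_BASE_RGB, scale=plant_scale
            )
            if painted is not None:
                rows_list.append(painted[0])
                cols_list.append(painted[1])
        if rows_list:
            rr = np.concatenate(rows_list)
            cc = np.concatenate(cols_list)
            y1, y2 = int(rr.min()), int(rr.max()) + 1
            x1, x2 = int(cc.min()), int(cc.max()) + 1
        else:  # fully off-canvas placement: keep a minimal box at the center
            y1 = int(np.clip(cy, 0, fh - 1))
            x1 = int(np.clip(cx, 0, fw - 1))
            y2, x2 = y1 + 1, x1 + 1
        boxes.append(
            (
                0,
                (x1 + x2) / 2 / fw,
                (y1 + y2) / 2 / fh,
                (x2 - x1) / fw,
                (y2 - y1) / fh,
            )
        )

    if spec.illumination_gradient > 0:
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:fh, 0:fw]
        ramp = np.cos(theta) * (xx / fw - 0.5) + np.sin(theta) * (yy / fh - 0.5)
        img *= (1.0 + spec.illumination_gradient * ramp)[..., None]

    if ss > 1:
        # sensor integration: each output pixel averages its ss×ss ground
        # footprint, diluting sub-pixel leaves into mixed plant/soil pixels
        img = downscale_local_mean(img, (ss, ss, 1))
        veg_mask = downscale_local_mean(veg_mask.astype(np.float64), (ss, ss)) >= 0.5

    if spec.psf_sigma_px > 0:
        # sensor blur is fixed in pixels, so it smears over more ground
        # (and relatively more of each plant) the higher the flight
        img = gaussian_filter(img, sigma=(spec.psf_sigma_px, spec.psf_sigma_px, 0))

    if spec.noise_sd > 0:
        img += rng.normal(0, spec.noise_sd, size=img.shape)

    img = np.clip(img, 0, 255).astype(np.uint8)
    truth = GroundTruth(boxes=boxes)
    if return_mask:
        return img, truth, veg_mask
    return img, truth


def scene_seed(root_seed: int, altitude_index: int, image_index: int) -> int:
    """Deterministic per-image seed derived from the dataset root seed."""
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(altitude_index, image_index))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    spec_template: SceneSpec,
    n_images_per_altitude: int,
    altitudes: tuple[float, ...] = (15.0, 30.0, 45.0),
    out_dir: str | Path = "dataset",
    count_jitter: float = 0.4,
    split_ratio: str = "2:1",
) -> pd.DataFrame:
    """Generate a multi-altitude image dataset with labels and a manifest.

    The template's ``image_size`` is interpreted at the template's own
    altitude; every generated image covers that same ground footprint, so
    the pixel frame shrinks as altitude grows (the same field plot imaged
    from higher up), exactly as when fixed plots are cropped from
    orthophotos flown at different heights.  Per-image seedling counts are
    drawn uniformly within ``±count_jitter`` of the template count so that
    count regression has real between-image variance to explain.  Images
    are written as PNG, labels as YOLO TXT, and the manifest (path,
    altitude, count, split) as CSV.  Within each altitude the images are split train/validation at
    ``split_ratio`` (2:1 by default, so 36 images yield 24/12),
    reproducibly under the template seed.
    """
    if n_images_per_altitude < 1:
        raise ValueError("n_images_per_altitude must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    count_rng = np.random.default_rng(np.random.SeedSequence(entropy=spec_template.rng_seed, spawn_key=(999,)))
    ground_h_cm = spec_template.image_size[0] * spec_template.gsd_cm_per_px
    ground_w_cm = spec_template.image_size[1] * spec_template.gsd_cm_per_px
    rows = []
    for ai, alt in enumerate(altitudes):
        gsd = gsd_for_altitude(float(alt))
        size_px = (
            max(1, int(round(ground_h_cm / gsd))),
            max(1, int(round(ground_w_cm / gsd))),
        )
        for i in range(n_images_per_altitude):
            n_i = int(
                round(
                    spec_template.n_seedlings
                    * count_rng.uniform(1 - count_jitter, 1 + count_jitter)
                )
            )
            spec_i = replace(
                spec_template,
                altitude_m=float(alt),
                image_size=size_px,
                n_seedlings=max(0, n_i),
                rng_seed=scene_seed(spec_template.rng_seed, ai, i),
                gsd_cm_per_px=None,
            )
            img, truth = generate_scene(spec_i)
            stem = f"alt{int(round(alt)):02d}_img{i:03d}"
            image_path = out_dir / "images" / f"{stem}.png"
            label_path = out_dir / "labels" / f"{stem}.txt"
            iio.imwrite(image_path, img)
            dataset_io.write_yolo_labels(label_path, truth.boxes)
            rows.append(
                {
                    "image": str(image_path),
                    "label": str(label_path),
                    "altitude_m": float(alt),
                    "count": truth.count,
                    "height_px": img.shape[0],
                    "width_px": img.shape[1],
                    "scene_seed": spec_i.rng_seed,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest = dataset_io.split_dataset(
        manifest,
        ratio=split_ratio,
        stratify_by="altitude_m",
        rng_seed=spec_template.rng_seed,
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
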