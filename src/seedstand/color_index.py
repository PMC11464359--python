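"""Color vegetation indices on chromatic coordinates.

Green vegetation on brown soil separates well in a handful of scalar color
indices computed from the per-pixel *chromatic coordinates*

    r = R/(R+G+B),  g = G/(R+G+B),  b = B/(R+G+B),

which normalize away overall brightness so that shadows and illumination
gradients mostly cancel.  Eight indices widely used for vegetation/soil
segmentation of UAV RGB imagery are provided:

=========  ==========================  ==================
name       formula                     vegetation tail
=========  ==========================  ==================
EXG        2g - r - b                  high
Cg         0.4g - 0.3r - 0.1b          high
EXG_EXR    3g - 2.4r - b               high
EXR        1.4r - g                    low (excess *red*)
GBDI       g - b                       high
NGBDI      (g - b)/(g + b)             high
NGRDI      (g - r)/(g + r)             high
S          HSV saturation of the RGB   high
=========  ==========================  ==================

All indices except S depend only on the chromatic coordinates and are
therefore invariant to scaling all three channels of a pixel by a positive
constant.  S is the saturation channel of the standard HSV transform,
``1 - min(R,G,B)/max(R,G,B)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

INDEX_NAMES: tuple[str, ...] = (
    "EXG",
    "Cg",
    "EXG_EXR",
    "EXR",
    "GBDI",
    "NGBDI",
    "NGRDI",
    "S",
)

#: which tail of each index's distribution corresponds to plants
VEGETATION_POLARITY: dict[str, str] = {name: "high" for name in INDEX_NAMES}
VEGETATION_POLARITY["EXR"] = "low"


@dataclass
class ChromaticImage:
    """Per-pixel channel shares of an RGB image.

    ``r + g + b == 1`` wherever the channel sum is nonzero.  Black pixels
    (zero channel sum) carry no color evidence; they are mapped to
    ``r = g = b = 0`` and flagged in ``zero_sum``.
    """

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    zero_sum: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape


@dataclass
class IndexImage:
    """A single color index applied pixelwise to an image."""

    values: np.ndarray
    index_name: str
    vegetation_polarity: str  # "high" or "low"


def to_chromatic(image: np.ndarray) -> ChromaticImage:
    """Convert an H×W×3 RGB raster (channels in 0..255) to chromatic coordinates.

    Parameters
    ----------
    image
        Integer or float array of shape (H, W, 3) with channel values in
        [0, 255].

    Returns
    -------
    ChromaticImage
        Channel shares r, g, b as float64 rasters, plus the zero-sum flag.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {image.shape}")
    rgb = image.astype(np.float64)
    total = rgb.sum(axis=2)
    zero_sum = total == 0
    safe = np.where(zero_sum, 1.0, total)
    r = np.where(zero_sum, 0.0, rgb[..., 0] / safe)
    g = np.where(zero_sum, 0.0, rgb[..., 1] / safe)
    b = np.where(zero_sum, 0.0, rgb[..., 2] / safe)
    return ChromaticImage(r=r, g=g, b=b, zero_sum=zero_sum)


def _saturation(original: np.ndarray) -> np.ndarray:
    rgb = np.asarray(original, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {rgb.shape}")
    return rgb2hsv(rgb / 255.0)[..., 1]


def compute_index(
    chromatic: ChromaticImage,
    name: str,
    original: np.ndarray | None = None,
) -> IndexImage:
    """Compute one of the eight color indices as an H×W raster.

    ``original`` (the raw RGB image) is required only for ``S``, which is
    defined on the HSV transform of the original channels rather than on
    chromatic coordinates.  Black (zero-sum) pixels yield 0 for every index.
    """
    if name not in INDEX_NAMES:
        raise ValueError(f"unknown color index {name!r}; expected one of {INDEX_NAMES}")
    r, g, b = chromatic.r, chromatic.g, chromatic.b
    if name == "EXG":
        values = 2.0 * g - r - b
    elif name == "Cg":
        values = 0.4 * g - 0.3 * r - 0.1 * b
    elif name == "EXG_EXR":
        values = 3.0 * g - 2.4 * r - b
    elif name == "EXR":
        values = 1.4 * r - g
    elif name == "GBDI":
        values = g - b
    elif name == "NGBDI":
        denom = g + b
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(denom == 0, 0.0, (g - b) / np.where(denom == 0, 1.0, denom))
    elif name == "NGRDI":
        denom = g + r
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(denom == 0, 0.0, (g - r) / np.where(denom == 0, 1.0, denom))
    else:  # S
        if original is None:
            raise ValueError("the S index requires the original RGB image")
        values = _saturation(original)
    values = np.where(chromatic.zero_sum, 0.0, values)
    return IndexImage(
        values=values,
        index_name=name,
        vegetation_polarity=VEGETATION_POLARITY[name],
    )


def compute_all_indices(image: np.ndarray) -> dict[str, IndexImage]:
    """Compute every index of the catalogue for one RGB image."""
    chromatic = to_chromatic(image)
    return {
        name: compute_index(chromatic, name, original=image) for name in INDEX_NAMES
    }
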