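"""Maximum inter-class variance (Otsu) thresholding and index separability.

An image of gray levels 0..255 is split at a threshold ``T`` into class 0
(levels <= T) and class 1 (levels > T).  With class proportions w0, w1 and
class mean levels mu0, mu1, the global mean is mu = w0*mu0 + w1*mu1 and the
inter-class variance is

    S(T) = w0*(mu0 - mu)^2 + w1*(mu1 - mu)^2.

Otsu's threshold is the T maximizing S; ties are broken toward the smallest
T for determinism.  S(T) plus the within-class variance equals the total
variance at every T, so eta = S(T*)/total_variance lies in [0, 1] and is a
normalized measure of how bimodal (separable) the gray-level distribution
is — eta = 1 for a perfect two-valued image.

Real-valued index images are bridged to gray levels by a linear min–max
quantization to [0, 255] with half-up rounding.  ``separability_analysis``
turns the visual histogram comparison used to pick a working index into two
numbers per index: eta at the Otsu optimum of the pooled plant/soil patch
pixels, and the overlap of the normalized plant and soil histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .color_index import INDEX_NAMES, IndexImage, compute_all_indices

N_LEVELS = 256


@dataclass
class GrayImage:
    """Quantized gray-level raster with the linear mapping that produced it."""

    values: np.ndarray  # H×W int, levels in [0, 255]
    mapping: tuple[float, float]  # (min_val, max_val) of the source values
    constant: bool = False


@dataclass
class OtsuResult:
    T: int
    omega0: float
    omega1: float
    mu0: float
    mu1: float
    mu: float
    S: float
    eta: float
    degenerate: bool


@dataclass
class SeparabilityRecord:
    index_name: str
    eta_at_optimum: float
    histogram_overlap: float
    fg_histogram: np.ndarray = field(repr=False)
    bg_histogram: np.ndarray = field(repr=False)


@dataclass
class SeparabilityReport:
    """Per-index separability records, sorted by descending eta."""

    records: list[SeparabilityRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index_name": [r.index_name for r in self.records],
                "eta_at_optimum": [r.eta_at_optimum for r in self.records],
                "histogram_overlap": [r.histogram_overlap for r in self.records],
            }
        )

    def rank_of(self, index_name: str) -> int:
        """1-based rank of an index by eta (1 = most separable)."""
        for i, rec in enumerate(self.records):
            if rec.index_name == index_name:
                return i + 1
        raise KeyError(index_name)

    def __getitem__(self, index_name: str) -> SeparabilityRecord:
        for rec in self.records:
            if rec.index_name == index_name:
                return rec
        raise KeyError(index_name)


def quantize(index_image: IndexImage | np.ndarray, bins: int = N_LEVELS) -> GrayImage:
    """Linearly map a real-valued raster onto gray levels 0..bins-1.

    Rounding is half-up (0.5 rounds toward the larger level).  A constant
    raster maps to all zeros with the ``constant`` flag set.  NaN or Inf
    pixels raise a ValueError.
    """
    values = index_image.values if isinstance(index_image, IndexImage) else index_image
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot quantize an empty image")
    if not np.all(np.isfinite(values)):
        raise ValueError("index image contains NaN or Inf pixels")
    lo = float(values.min())
    hi = float(values.max())
    if hi == lo:
        return GrayImage(
            values=np.zeros(values.shape, dtype=np.int64),
            mapping=(lo, hi),
            constant=True,
        )
    scaled = (values - lo) * ((bins - 1) / (hi - lo))
    levels = np.floor(scaled + 0.5).astype(np.int64)  # round half up
    np.clip(levels, 0, bins - 1, out=levels)
    return GrayImage(values=levels, mapping=(lo, hi), constant=False)


def gray_histogram(gray: GrayImage | np.ndarray, bins: int = N_LEVELS) -> np.ndarray:
    values = gray.values if isinstance(gray, GrayImage) else np.asarray(gray)
    if values.size == 0:
        raise ValueError("empty image has no histogram")
    return np.bincount(values.ravel().astype(np.int64), minlength=bins).astype(np.int64)


def threshold_curves(hist: np.ndarray) -> dict[str, np.ndarray]:
    """Class statistics for every candidate threshold t = 0..255.

    Computed from exact integer cumulative sums of the histogram, so the
    per-threshold statistics carry no accumulation error beyond the final
    float divisions.  Thresholds whose class 0 or class 1 is empty get
    S = 0 (no split).  Returns arrays ``omega0, omega1, mu0, mu1, mu, S,
    within`` of length 256, where ``within`` is the pooled within-class
    variance w0*var0 + w1*var1.
    """
    hist = np.asarray(hist, dtype=np.int64)
    if hist.ndim != 1 or hist.size != N_LEVELS:
        raise ValueError(f"expected a length-{N_LEVELS} histogram")
    if hist.sum() == 0:
        raise ValueError("histogram is empty")
    levels = np.arange(N_LEVELS, dtype=np.int64)
    n0 = np.cumsum(hist)  # pixels at level <= t
    total = n0[-1]
    sum0 = np.cumsum(levels * hist)
    sumsq0 = np.cumsum(levels * levels * hist)
    n1 = total - n0
    sum1 = sum0[-1] - sum0
    sumsq1 = sumsq0[-1] - sumsq0

    omega0 = n0 / total
    omega1 = n1 / total
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(n0 > 0, sum0 / np.where(n0 > 0, n0, 1), 0.0)
        mu1 = np.where(n1 > 0, sum1 / np.where(n1 > 0, n1, 1), 0.0)
        var0 = np.where(n0 > 0, sumsq0 / np.where(n0 > 0, n0, 1) - mu0 * mu0, 0.0)
        var1 = np.where(n1 > 0, sumsq1 / np.where(n1 > 0, n1, 1) - mu1 * mu1, 0.0)
    mu = omega0 * mu0 + omega1 * mu1
    d0 = mu0 - mu
    d1 = mu1 - mu
    S = omega0 * (d0 * d0) + omega1 * (d1 * d1)
    S = np.where((n0 == 0) | (n1 == 0), 0.0, S)
    within = omega0 * var0 + omega1 * var1
    return {
        "omega0": omega0,
        "omega1": omega1,
        "mu0": mu0,
        "mu1": mu1,
        "mu": mu,
        "S": S,
        "within": within,
    }


def total_variance(hist: np.ndarray) -> float:
    hist = np.asarray(hist, dtype=np.int64)
    levels = np.arange(N_LEVELS, dtype=np.float64)
    total = hist.sum()
    mean = float((levels * hist).sum() / total)
    return float((hist * (levels - mean) ** 2).sum() / total)


def otsu_from_histogram(hist: np.ndarray) -> OtsuResult:
    """Otsu's threshold from a 256-bin histogram of gray levels."""
    curves = threshold_curves(hist)
    S = curves["S"]
    tot_var = total_variance(hist)
    if tot_var == 0.0:
        # constant image: no contrast, no meaningful split
        t = 0
        return OtsuResult(
            T=t,
            omega0=float(curves["omega0"][t]),
            omega1=float(curves["omega1"][t]),
            mu0=float(curves["mu0"][t]),
            mu1=float(curves["mu1"][t]),
            mu=float(curves["mu"][t]),
            S=0.0,
            eta=0.0,
            degenerate=True,
        )
    t = int(np.argmax(S))  # argmax returns the first (smallest) maximizer
    return OtsuResult(
        T=t,
        omega0=float(curves["omega0"][t]),
        omega1=float(curves["omega1"][t]),
        mu0=float(curves["mu0"][t]),
        mu1=float(curves["mu1"][t]),
        mu=float(curves["mu"][t]),
        S=float(S[t]),
        eta=float(S[t] / tot_var),
        degenerate=False,
    )


def otsu_threshold(gray: GrayImage | np.ndarray) -> OtsuResult:
    """Otsu's threshold of a gray-level image (class 0 = levels <= T)."""
    return otsu_from_histogram(gray_histogram(gray))


def segment(index_image: IndexImage) -> np.ndarray:
    """Binary vegetation mask of an index image via quantization + Otsu.

    The mask is oriented by the index's vegetation polarity so that True
    always means plant: for high-polarity indices the foreground is the
    class above the threshold, for the excess-red index it is the class at
    or below it.  A degenerate (constant) image yields an all-background
    mask.
    """
    gray = quantize(index_image)
    result = otsu_threshold(gray)
    if result.degenerate or gray.constant:
        return np.zeros(gray.values.shape, dtype=bool)
    if index_image.vegetation_polarity == "high":
        return gray.values > result.T
    return gray.values <= result.T


def _gather_patch_pixels(
    raster: np.ndarray,
    patches: list[tuple[int, int]],
    patch_size: int,
) -> np.ndarray:
    h, w = raster.shape
    pixels = []
    for row, col in patches:
        if row < 0 or col < 0 or row + patch_size > h or col + patch_size > w:
            raise ValueError(
                f"patch at ({row}, {col}) of size {patch_size} exceeds image bounds {raster.shape}"
            )
        pixels.append(raster[row : row + patch_size, col : col + patch_size].ravel())
    return np.concatenate(pixels)


def separability_analysis(
    image: np.ndarray,
    fg_patches: list[tuple[int, int]],
    bg_patches: list[tuple[int, int]],
    patch_size: int = 20,
) -> SeparabilityReport:
    """Score how well each color index separates plant from soil pixels.

    ``fg_patches`` / ``bg_patches`` are top-left (row, col) corners of
    square patches of known plant and soil pixels.  For each index the
    patch pixels are pooled, quantized to 256 levels over a robust range
    (0.5th–99.5th percentile of the pooled values, so a few outlier pixels
    cannot squeeze the bulk of both classes into a handful of bins), and
    scored by (a) Otsu's normalized criterion eta on the pooled histogram
    and (b) the overlap sum(min(fg_bin, bg_bin)) of the normalized class
    histograms.  Records are sorted by descending eta.
    """
    if not fg_patches or not bg_patches:
        raise ValueError("need at least one patch of each class")
    indices = compute_all_indices(image)
    records = []
    for name in INDEX_NAMES:
        raster = indices[name].values
        fg = _gather_patch_pixels(raster, fg_patches, patch_size)
        bg = _gather_patch_pixels(raster, bg_patches, patch_size)
        pooled = np.concatenate([fg, bg])
        lo, hi = np.percentile(pooled, [0.5, 99.5])
        pooled = np.clip(pooled, lo, hi)
        gray = quantize(IndexImage(pooled, name, indices[name].vegetation_polarity))
        if gray.constant:
            eta = 0.0
            fg_hist = np.zeros(N_LEVELS)
            fg_hist[0] = 1.0
            bg_hist = fg_hist.copy()
        else:
            result = otsu_from_histogram(gray_histogram(gray))
            eta = result.eta
            fg_levels = gray.values[: fg.size]
            bg_levels = gray.values[fg.size :]
            fg_hist = np.bincount(fg_levels, minlength=N_LEVELS) / fg.size
            bg_hist = np.bincount(bg_levels, minlength=N_LEVELS) / bg.size
        overlap = float(np.minimum(fg_hist, bg_hist).sum())
        records.append(
            SeparabilityRecord(
                index_name=name,
                eta_at_optimum=float(eta),
                histogram_overlap=overlap,
                fg_histogram=fg_hist,
                bg_histogram=bg_hist,
            )
        )
    records.sort(key=lambda r: -r.eta_at_optimum)
    return SeparabilityReport(records=records)
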