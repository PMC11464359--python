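# Methods

## The counting problem

The quantity of interest is the stand count: the number of established
seedlings per plot, observed as green rosettes on brown soil in nadir RGB
imagery flown at 15, 30 or 45 m. One pixel covers more ground the higher
the flight (ground sample distance, GSD, grows linearly with altitude), so
a seedling's pixel footprint shrinks with the square of altitude and every
stage of the pipeline — segmentation, classification, component counting —
operates closer to the resolution limit. The package measures how count
recovery degrades along that axis.

## Color indices and chromatic coordinates

All indices except HSV saturation are defined on chromatic coordinates
r = R/(R+G+B) etc., which removes multiplicative brightness: shadows,
vignetting and illumination gradients scale all three channels together
and cancel exactly. Black pixels (zero channel sum) carry no color
evidence and are defined as 0 for every index, with a flag. Excess red is
the one index whose *low* tail is vegetation; the segmentation layer
orients every mask so that foreground always means plant.

Saturation has no chromatic formula; the standard HSV definition
S = 1 − min(R,G,B)/max(R,G,B) is used on the raw channels.

## Otsu thresholding

Real-valued index images are linearly quantized to 256 gray levels
(min–max, half-up rounding; constant images are flagged and map to zero).
Threshold statistics are computed from exact int64 cumulative sums of the
histogram, so ω₀+ω₁ = 1 and μ = ω₀μ₀+ω₁μ₁ hold to the last bit and the
decomposition S(t) + within-class variance(t) = total variance holds to
1e−9 at every candidate threshold. Class 0 is "level ≤ t" (the convention
matters only for tie pixels); equal-S ties resolve to the smallest t; a
zero-variance image is degenerate (T = 0, η = 0, all-background mask).
Otsu runs per image, not globally across a flight.

## Separability scoring

The visual judgment "which index separates plants from soil" is made
quantitative on 20×20 px patches of known class: for each index the pooled
patch pixels are quantized over a robust range (0.5th–99.5th percentile,
so a handful of outlier pixels cannot compress both classes into a few
bins) and scored by η at the Otsu optimum plus the overlap
Σ min(fg_bin, bg_bin) of the normalized class histograms. Plant patches
are chosen purity-first (a bounding box of a rosette is ~half soil; a
human picking sample patches would avoid that soil, and the synthetic
ground-truth mask lets the analysis do the same).

On default scenes EXG, EXG−EXR, Cg, NGRDI and EXR form a near-collinear
cluster with η ≈ 0.85–0.92; their internal ranking varies with patch
sampling and is not meaningful. The blue-difference indices (GBDI, NGBDI)
and saturation separate visibly worse because soil wet/dry mottling and
canopy shade both move the blue share while leaving the green share
almost untouched.

## The SVM counting path

Per-pixel features are (r, g, b, EXG); adding further indices is a config
knob. Training patches: plant patches fully inside ground-truth boxes,
soil patches intersecting no box, patch side 20 px at 15 m scaled linearly
with GSD. Because box interiors contain inter-leaf soil, per-pixel labels
inside plant patches are refined by an Otsu threshold on the pooled patch
EXG values — the pooled patches are roughly half plant, the bimodal regime
where that threshold is reliable even when the whole frame is ~98% soil.
The unrefined mode (`refine_labels=None`) is retained; it pushes the
decision boundary into the soil cloud and produces heavy false positives,
which is itself informative about box-level weak supervision.

The classifier is a soft-margin SVM (C = 1, linear kernel by default, RBF
available) on standardized features; for the linear kernel whole-image
classification evaluates the primal weights directly. The binary map is
cleaned by morphological opening (square element) and 8-connected
components above a minimum area become detections, each with a box and a
confidence min(1, area/median area) so that AP is computable for this
detector too.

Scale-dependent parameters derive from their 15 m base values: minimum
component area 25 px scaling with (15/altitude)², floored at 4 px (a
smaller component is indistinguishable from noise at any GSD); opening
radius 0 by default — on these clean masks area gating suffices, and a
3×3 opening at 15 m erodes the smallest seedlings; patch side linearly.

## Evaluation

Matching is greedy and one-to-one: predictions in descending confidence
order each take the unmatched ground truth of highest IoU ≥ 0.5 (half-open
pixel boxes; normalized YOLO coordinates are converted through the image
size first). P, R, F1 use the 0/0 → 0 convention so batch evaluation is
total. AP integrates the all-point precision envelope over the confidence
sweep and is pinned by a brute-force cutoff-enumeration oracle in the
tests; mAP averages per-class AP (one class here, so mAP = AP). Count
recovery uses R² = 1 − Σ(Yᵢ−Xᵢ)²/Σ(Yᵢ−Ȳ)² — note this compares X to Y
directly, so systematic bias (e.g. merged neighbors) costs R² even when
the relationship is perfectly linear — plus RMSE and RRMSE = RMSE/Ȳ
reported in percent. R² is undefined (raises) when all true counts are
equal.

## The synthetic scene model

What it emulates, and the defaults (all lengths physical, converted
through the GSD of 0.5 cm/px at 15 m):

- **Plants**: 4–7 elliptical leaves radiating from a core, leaf length
  4–7 cm, per-plant emergence scale U(0.55, 1.25) (real stands have
  runts; the small ones sit at the detection limit at 45 m). Leaf color
  jitters around a green mode; each leaf carries a random canopy-shade
  factor that darkens it and shifts it bluer (skylight illumination) while
  leaving the green share stable.
- **Layout**: rows 0.6 m apart; in-row spacing U(22, 32) cm (≈ 3.7
  plants/m of row, a typical transplant density); a fraction
  `overlap_fraction` = 0.08 of plants is instead placed 6–10 cm from its
  neighbor, producing genuinely merged masks — the dominant undercount
  mechanism. Placement raises if the requested count cannot fit.
- **Soil**: a brown base modulated by low-frequency clod brightness,
  pixel speckle, and wet/dry mottling that trades red against blue by
  equal amounts so the green share (hence EXG) stays clean — wetness in
  nature darkens and blues soil, and modeling it asymmetrically makes
  soil EXG bimodal, which is an artifact rather than physics.
- **Imaging**: scenes coarser than the reference GSD are rendered at the
  reference resolution and block-averaged to the target grid (sensor
  integration: thin leaves dilute into mixed pixels — the physical reason
  small seedlings vanish at altitude), then blurred with a 0.7 px PSF,
  given a ±15% linear illumination gradient, and degraded with Gaussian
  sensor noise (σ = 6 DN).
- **Weeds**: smaller, yellower two/three-leaf blobs at 0.05/m²,
  unlabeled — false-positive pressure.
- **Datasets**: the template frame (600×960 px at 15 m = 3.0 m × 4.8 m)
  fixes the ground footprint; every altitude covers the same ground with
  proportionally fewer pixels, as when fixed plots are cropped from
  orthophotos flown at different heights. Per-image counts jitter
  uniformly ±40% around the template's 60 so count regression has real
  variance to explain. Splitting is stratified by altitude at 2:1
  (train = ⌈2n/3⌉; 36 images → 24/12; a single image goes to train with
  a warning).

Everything is a pure function of the seed: scenes are bit-identical under
the same spec, datasets under the same template, and the experiment's
results CSV is byte-identical across reruns.

What it does **not** emulate: real sorghum morphology, specular leaf
highlights, orthophoto stitching seams and lateral/heading overlap,
multispectral channels, camera color response, or labeling error. Passing
tests therefore certify the pipeline's arithmetic and its qualitative
altitude behaviour, not field-ready accuracy on real imagery.

## Experiment design and expected behaviour

The default experiment generates 36 images at each of 15/30/45 m, trains
the pixel SVM per altitude on patches from 3 training images, and scores
both counting paths on the 12 validation images per altitude. Problem
sizes were chosen so the full experiment runs in about a minute on one
CPU.

At the default seed the SVM path gives count R² 0.93/0.88/0.85 at
15/30/45 m with detection F1 0.97/0.88/0.79 — monotone degradation driven
by blur-merged neighbors and vanished runts. With only 12 validation
images the 15-vs-30 m or 30-vs-45 m ordering can invert by ~0.01 under
reseeding; the decline is the mean behaviour, the detection metrics
degrade monotonically at every seed tried. The whole-image Otsu path
collapses at 30–45 m (vegetation ≈ 1.5% of the frame; after mixed-pixel
dilution the plant mode's inter-class variance falls below soil-internal
splits), the classical failure mode of global thresholding on
small-target imagery; at 15 m it matches the SVM path.

## Numerical and degenerate-input conventions

- Quantization rounds half up; constant rasters are flagged, not errors.
- NGBDI/NGRDI denominators cannot vanish for non-black pixels under
  chromatic coordinates but are guarded to 0 anyway.
- Component confidence is clipped into (0, 1]; an empty mask yields count
  0 with an empty detection list.
- Ratios parse strictly ("a:b", positive integers); label files round-trip
  exactly because floats are written with Python's shortest
  round-tripping representation.
- SVM training is deterministic given samples and config; duplication of
  a separable sample set leaves the margin unchanged (checked at libsvm's
  solver tolerance).

## Known limitations

- The Otsu counting path is unreliable below ~3% vegetation cover; the
  package reports its failure rather than masking it.
- Merged neighbors are counted as one; no watershed or shape-based
  splitting is attempted, so dense stands bias counts low.
- The component-confidence definition is a pragmatic declaration (needed
  so AP is computable for the SVM detector), not an estimate of class
  probability.
- Deep-learning detectors are out of scope; externally produced
  YOLO-format prediction files can still be scored via
  `evaluation.score_prediction_files`.
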