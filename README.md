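# seedstand

Stand counting of row-crop seedlings in nadir UAV RGB imagery.

Breeders and agronomists estimate crop emergence by counting established
seedlings per plot. Doing this from low-altitude drone imagery replaces
manual field counts, but the result depends strongly on flight altitude:
the higher the flight, the fewer pixels per plant, and the more counting
degrades. `seedstand` implements the classical color-index counting
pipeline end to end and quantifies exactly that altitude dependence — on
synthetic field imagery with exact ground truth, so every stage is
testable without any drone data.

The pipeline:

1. **Color vegetation indices.** Each pixel's chromatic coordinates
   r = R/(R+G+B), g = G/(R+G+B), b = B/(R+G+B) feed eight standard
   indices — EXG (2g − r − b), EXR (1.4r − g), EXG−EXR, Cg, GBDI, NGBDI,
   NGRDI, and HSV saturation — that separate green vegetation from brown
   soil independently of brightness.
2. **Otsu segmentation.** An index image is quantized to 256 gray levels
   and thresholded at the T maximizing the inter-class variance
   S(T) = ω₀(μ₀ − μ)² + ω₁(μ₁ − μ)². The normalized criterion
   η = S(T*)/σ²_total and the plant/soil histogram overlap rank the
   indices by separability; excess green wins on these scenes.
3. **SVM pixel classification.** A maximum-margin linear classifier on
   per-pixel color features (r, g, b, EXG), trained on plant/soil patches
   whose labels are refined by the index segmentation, classifies every
   pixel; morphological cleanup and 8-connected component labeling with a
   minimum-area gate turn the mask into per-seedling detections.
4. **Evaluation.** Greedy IoU matching at 0.5 gives P = TP/(TP+FP),
   R = TP/(TP+FN), F1, and AP/mAP@0.5; per-image counts X_i against truth
   Y_i give R² = 1 − Σ(Y_i−X_i)²/Σ(Y_i−Ȳ)², RMSE, and RRMSE = RMSE/Ȳ.
5. **Synthetic fields.** Row-planted multi-leaf rosettes (0.6 m row
   spacing) on textured soil, rendered at a 0.5 cm/px reference ground
   sample distance and area-averaged down to the target altitude's GSD,
   with neighbor overlap, emergence variability, canopy shading,
   illumination gradients, sensor noise, and unlabeled weeds.

## Worked example

```bash
python analysis/01_generate_dataset.py   --seed 0   # 108 images + labels + manifest
python analysis/02_index_separability.py --seed 0   # which index to threshold
python analysis/03_count_and_evaluate.py --seed 0   # the altitude experiment
```

The separability step ranks the indices on pure plant/soil patches:

```
index_name  eta_at_optimum  histogram_overlap
       EXG        0.899185           0.215000
   EXG_EXR        0.897023           0.246875
        Cg        0.895367           0.252812
     NGRDI        0.874644           0.283750
       EXR        0.856382           0.290625
     NGBDI        0.730856           0.500000
         S        0.726443           0.438438
      GBDI        0.714848           0.343437
```

Excess green and its linear relatives separate plants from soil almost
perfectly (η ≈ 0.9), while the blue-difference indices overlap heavily —
which is why the pipeline thresholds EXG.

The altitude experiment (36 images per altitude, 24 train / 12 validation
each) then prints:

```
method  altitude_m     P     R  mAP50    F1        R2    RMSE  RRMSE_pct  n_val
  otsu        15.0 0.994 0.951  0.946 0.972     0.928   3.014      5.326     12
   svm        15.0 0.992 0.951  0.944 0.971     0.932   2.915      5.153     12
  otsu        30.0 0.469 0.861  0.591 0.607  -270.971 190.562    306.124     12
   svm        30.0 0.909 0.857  0.844 0.882     0.883   3.948      6.341     12
  otsu        45.0 0.051 0.434  0.067 0.091 -1715.469 600.253   1024.614     12
   svm        45.0 0.823 0.750  0.703 0.785     0.850   5.620      9.593     12

SVM count R² by altitude: 15 m: 0.932, 30 m: 0.883, 45 m: 0.850 — count
recovery decreases with altitude.
```

Two findings to read off: the supervised SVM path degrades gracefully with
altitude (R² 0.93 → 0.88 → 0.85, detection F1 0.97 → 0.88 → 0.79) as
seedlings shrink toward the resolution limit; and the unsupervised
whole-image Otsu path collapses at 30–45 m, where vegetation covers so
little of the frame that the threshold falls inside the soil distribution
— the textbook fragility of global thresholding, and the reason the
supervised path exists.

## Layout

- `src/seedstand/` — the library: `synthetic_field`, `color_index`,
  `otsu`, `svm_counter`, `evaluation`, `dataset_io`, `experiment`.
- `analysis/` — the numbered drivers shown above.
- `tests/` — unit, property, and end-to-end suites.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
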