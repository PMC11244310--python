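# gravessel

Unsupervised retinal blood-vessel segmentation for fundus photographs,
built on grey relational analysis (GRA) — a similarity calculus from grey
system theory in which a comparison value x is scored against a reference
x₀ by the coefficient

    γ(x₀, x) = 1 / (1 + |x₀ − x|),   γ ∈ (0, 1],

evaluated on the 8-bit intensity scale.  The package is aimed at medical
image-analysis practitioners who need a deterministic, training-free vessel
segmenter plus the standard evaluation metrics, and at method developers who
need a reproducible baseline with a built-in synthetic fundus generator (no
dataset downloads required to run every stage).

## Method

The pipeline runs five stages in fixed order:

1. **Green channel** — the plane with the best vessel/background contrast.
2. **NADF-GRA noise filter** — for each pixel, the nine coefficients of its
   3×3 window against the window median v are sorted ascending (the
   *association order*); a center ranking among the three smallest is an
   impulse-noise candidate (flag 0).  Flagged pixels are replaced by the
   grey-weighted mean of their normal neighbours, Σγₕfₕ / Σγₕ with
   γₕ = 1/(1+|v−fₕ|), falling back to a 5×5 median inside noise blocks.
   Traversal is raster-order and in place, so repairs feed later windows.
3. **CLAHE** — contrast-limited adaptive histogram equalization
   (8×8 tiles, clip 0.01).
4. **Frangi vesselness** — multi-scale Hessian eigenvalue filtering tuned to
   dark curvilinear ridges, rescaled to 0–255 with vessels bright.
5. **TS-GRA segmentation** — per pixel, the grey relational *degree*
   γ(i,j) = (1/9) Σᵤ 1/(1+|x̄−xᵤ|) against the 3×3 window mean x̄; the degree
   is 1 on locally constant neighbourhoods and small across edges, and pixels
   with γ(i,j) < θ are marked as vessel/edge points.  Morphological
   post-processing (disc closing, bounded cavity filling, removal of
   components under 70 px) produces the final mask.

Predicted masks are scored against a manual gold standard with
Se, Sp, Acc, Pr, F1 and the Jaccard coefficient, restricted to the
camera field of view (FOV) when a mask is available.

## Worked example

Generate two synthetic fundus samples and segment them:

```bash
gravessel synth --out demo --n 2 --seed 42
mkdir -p flat/img flat/truth flat/fov
for k in 000 001; do
  cp demo/sample_$k/image.png flat/img/s$k.png
  cp demo/sample_$k/truth.png flat/truth/s$k.png
  cp demo/sample_$k/fov.png   flat/fov/s$k.png
done
gravessel run --in flat/img --out out --truth-dir flat/truth --fov-dir flat/fov
```

prints (and writes to `out/report.csv`):

```
  image   TP    TN   FP  FN      Acc       Se       Sp       Pr       F1       JC
   s000 1878 43580 1827 175 0.957817 0.914759 0.959764 0.506883 0.652310 0.484021
   s001 6106 32966 8335  53 0.823262 0.991395 0.798189 0.422824 0.592816 0.421278
Average                     0.890539 0.953077 0.878976 0.464853 0.622563 0.452649
```

Each row compares one predicted mask with its pixel-aligned ground truth
inside the circular FOV: `Se` is the fraction of true vessel pixels
recovered, `Sp` the fraction of background kept clean, `Acc` the overall
pixel accuracy, and `F1`/`JC` summarize the overlap between mask and truth.
The `Average` row is the unweighted mean over images.  On real fundus
images (DRIVE/STARE/HRF directory layouts are supported via `--layout`),
point `--in/--truth-dir/--fov-dir` at the dataset folders.

The same stages are available individually (`gravessel denoise`, `enhance`,
`segment`, `postprocess`, `eval`) and as library functions
(`gravessel.run_pipeline`, `nadf_gra`, `ts_gra_segment`, ...).

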