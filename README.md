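# pectseg — shape-based pectoral muscle boundary detection in MLO mammograms

In the medio-lateral-oblique (MLO) mammographic view the pectoral muscle
appears as a bright, roughly triangular region across the upper posterior
corner, narrowing from top to bottom.  Because its texture and intensity
rival dense parenchyma, it must be segmented out before computer-aided
analysis of the breast — yet its boundary varies widely in slope, curvature
and contrast.  `pectseg` implements an automatic, shape-prior-driven
detector of that boundary for researchers working on mammogram
preprocessing pipelines, together with evaluation metrics and a synthetic
phantom generator so the whole pipeline can be tested without clinical
data.

## Method

1. **Shape-based enhancement mask (SBEM).**  The image is filtered with

   `g(x,y) = Σ_{s=0}^{M} Σ_{t=1}^{N} w_{s,t} · (I(x+s, y−t) − I(x+s, y+t)) + w_c · I(x,y)`

   an antisymmetric weighted difference of `N` horizontal pixel pairs over
   `M+1` rows, plus a center contribution `w_c ∈ [0,1]`.  The pair
   coefficients sum to zero, so homogeneous regions respond with exactly
   `w_c·I` while left-bright transitions — the muscle edge after
   orientation normalization — peak strongly.  The lower mask rows are
   shifted one column left to match the muscle's narrowing shape.
   Defaults: `w_{s,1}=1, w_{s,2}=2, w_{s,3}=0`, `w_c=0.5` (a 7×2 kernel).

2. **Seed-point selection.**  In the top `P=100` rows of the enhanced
   image, the `Q=12` largest values per row are kept; morphological-gradient
   edges of the result are labeled, and the initial boundary is chosen by a
   cascade: slanted orientation (15°–90°, down-left), largest pixel count,
   highest mean source intensity, and — for multi-layer muscles — the
   rightmost edge.  The seed is the top-right pixel of that component.

3. **Constrained growth and cubic fit.**  From the seed, the boundary
   advances `K_step=2` rows at a time to the best of `W_band=6` candidate
   columns (five at/left of the current column, one right), following the
   enhanced ridge until it nears the left image edge.  The grown points are
   least-squares fitted with a cubic `column(row)` polynomial, sampled at
   every row, and rasterized into the muscle region (muscle = pixels
   strictly left of the boundary).

4. **Evaluation.**  Against a ground-truth region `R`, a detection `D` is
   scored by FP rate `(|D∪R|−|R|)/|R|`, FN rate `(|D∪R|−|D|)/|R|`, their
   sum (total mismatch), and the Hausdorff distance between boundary point
   sets, in mm via the pixel spacing.

## Worked example

```bash
python examples/02_detect_on_phantom.py
```

```
status          : ok
seed point      : (0, 232) (row, column)
selection rule  : pixel-count
grown points    : 141 seeds, fitted to 288 boundary rows
mean |column error| vs truth: 0.16 px
FP 0.01%  FN 0.14%  total 0.14%  Hausdorff 0.40 mm
```

A noisy 512×512 phantom (Gaussian noise sd 8, three glandular clutter
blobs) is generated with a known linear boundary; the detector recovers it
to 0.16 px mean column error.  FP/FN are the percentages of falsely
added/missed pixels relative to the true muscle area, and 0.40 mm
Hausdorff means the worst boundary deviation is one pixel at the phantom's
0.4 mm spacing.  The other example scripts demonstrate the filter itself,
the metric definitions, and the multi-layer failure mode.

## Command line

```bash
pectseg phantom --n 5 --noise-sd 8 --blobs 3 --out phantoms/
pectseg detect phantoms/*.pgm --out detections/ --spacing 0.4
pectseg evaluate --pred detections/ --truth phantoms/ --spacing 0.4
```

`detect` accepts mini-MIAS-style PGM (and PNG) images, writes per-image
boundary CSVs, region masks, overlays and a summary CSV, and never aborts a
batch on a single detection failure.  All eleven pipeline parameters can be
overridden through a YAML config (`--config`); defaults are the standard
parameter set above.

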