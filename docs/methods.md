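# Methods

## Model and assumptions

The detector assumes an MLO mammogram in which the pectoral muscle is
(i) brighter than the surrounding breast tissue, (ii) roughly triangular,
occupying the top-left corner after orientation normalization, and
(iii) bounded by an edge whose column decreases weakly with row (slope
between roughly 15° and 90° from horizontal).  All coordinates are 0-based
(row, column) with row 0 at the top; every module shares this convention.

### Preprocessing

Images are normalized so the muscle sits top-left.  When no laterality
flag is supplied, the brighter of the left/right top-quarter column blocks
decides the side; a flip is a pure column reversal, so applying it twice
restores the original pixels.  Mammograms digitized at high resolution are
block-mean downsampled (mean over each `f×f` block, partial edge blocks
averaged over available pixels) rather than decimated — averaging
suppresses noise before filtering.  Pixel spacing is multiplied by the
factor, so mm-valued metrics stay correct.

### Enhancement filter

The shape-based enhancement mask computes an antisymmetric weighted
difference of `N` horizontal pixel pairs over `M+1` rows plus `w_c` times
the center pixel (see README for the formula).  Two exact laws follow from
the construction and are enforced by tests: the pair coefficients sum to
zero for *any* parameter choice, and a constant image `c` maps to exactly
`w_c·c`.  The implementation is a cross-correlation (no kernel flip), so
the index signs in the definition map literally onto the kernel; borders
use replicate padding because zero padding would fabricate a strong
bright-to-zero step at the left border — precisely where the muscle lies.
The output is kept real-valued and unclipped; downstream steps only rank
values.

Default geometry is `M=1, N=3` — a 7×2 kernel with weights
`w_{s,1}=1, w_{s,2}=2, w_{s,3}=0` and `w_c=0.5`.  The weight grows with
`t` to suppress tissue away from the edge; the outermost pair is zeroed so
the shifted variant keeps the zero-sum law.  For the shape-based variant
the lower row is displaced one column left per row (`shift_per_row=1`,
configurable), matching a boundary that loses about one column every one
to two rows at this kernel scale; vacated cells are zero-filled.  `w_c`
trades off edge response against brightness of homogeneous regions: large
values favor the (bright) inner layers of multi-layer muscles, small
values lose the seed-selection intensity cue, and 0.5 is the compromise
default.

### Seed-point selection

The search runs on the top `P=100` rows of the enhanced image, where the
boundary is cleanest.  Per row exactly the `Q=12` largest values survive
(ties at the cutoff broken leftmost-first, so the count is always exactly
`min(Q, n_cols)`).  Edges of the binary result are the morphological
gradient (binary minus its 3×3 erosion); 8-connectivity is used for
labeling because diagonal edges fragment under 4-connectivity, and
components under 3 pixels are dropped as speckle.

The initial boundary is selected by a cascade:

1. *Orientation*: keep components whose principal-axis angle from
   horizontal lies strictly in (15°, 90°) and whose (row, column)
   covariance is ≤ 0 (down-left slope).  The principal axis of the pixel
   scatter was chosen over line fitting as the angle estimator for ragged
   pixel sets; the 15° floor rejects horizontal tape and label edges.
2. *Pixel count*: largest component wins.
3. *Intensity*: if runners-up are within 10% of the largest count, the
   highest mean intensity wins — measured on the **original** image, since
   high gray level is a property of the muscle, not of the enhancement.
4. *Rightmost*: if those intensities are within 5% of each other the
   muscle is treated as multi-layer and the rightmost (outermost) edge
   wins.

The 10%/5% thresholds quantify "almost the same" and "similar"; both are
exposed in `SeedParams`.  The rule that fired is logged per image — the
multi-layer failure analysis depends on observing it.  The seed is the
top-right pixel of the winning component (minimum row, then maximum
column).  If no component passes the orientation filter the image is
reported as a detection failure rather than guessing.

### Constrained growth and fitting

From the seed the boundary advances `K_step=2` rows per step, scoring
`W_band=6` candidate columns on the enhanced image: the contiguous offsets
`−(left_bias−1) … +(W_band−left_bias)`, i.e. `−4 … +1` at the default
`left_bias=5`.  Five-of-six candidates at or left of the current column
encode the narrowing shape while the single `+1` permits slight rightward
drift.  Ties at the maximum go to the leftmost candidate (consistent with
narrowing); growth stops when the column comes within `stop_margin=5` of
the left edge or candidates run out of bounds.  Termination is guaranteed
since every step descends `K_step` rows.

The grown points are fitted with a least-squares cubic `column(row)`
(degree reduced when fewer than four points, logged), sampled at every
integer row from the first grown row, rounded to integers, clamped to the
image, and cut at the first row whose rounded column reaches 0.  The
sampling cut uses the *rounded* column to avoid floating-point dithering
at the zero crossing.  Rows above the first sample reuse its column when
rasterizing (constant extension; the seed sits within the top rows, so the
affected area is a few pixels), and rows below the last sample contain no
muscle.  Rasterization is half-open — muscle = columns strictly left of
the boundary; the boundary pixel itself is breast — stated once and used
identically by the phantom generator, so FP/FN are well defined.

### Evaluation

FP, FN and total mismatch rates are set arithmetic on equal-shaped masks,
normalized by the truth size (so FP is unbounded above while FN ≤ 100%);
`total = FP + FN` holds as an algebraic identity and is property-tested.
The Hausdorff distance operates on boundary *point sets* — the detected
and true polylines when available, otherwise mask outlines (mask minus its
3×3 erosion) — and is converted to mm with the post-downsampling pixel
spacing (0.4 mm for 1024×1024 images at 0.2 mm halved).  Undefined metrics
(empty truth, empty point sets) raise instead of returning sentinels so
broken ground truth surfaces in batch runs.

## Synthetic phantoms

`PhantomSpec` generates 512×512, 0.4 mm/pixel images — the working
resolution of a 1024×1024, 0.2 mm mammogram downsampled by two — with a
cubic ground-truth boundary `column(r) = a + b·r + c·r² + d·r³`, checked
monotone non-increasing.  The muscle adds a step of `muscle_base −
breast_base` (default 70 gray levels) over the breast plateau plus an
intensity ramp growing away from the boundary (default 30 levels at the
apex), a Gaussian blur of σ=1 px softening the step into a step-plus-
gradient transition, optional Gaussian noise, and optional glandular
clutter: Gaussian bumps with amplitudes 30–80% of the muscle step, kept
below muscle intensity so the intensity cue stays discriminative.
Multi-layer mode adds a nested inner edge at 55% of the boundary column
with `inner_contrast` times the outer step — below 1 for the usual dimmer
inner layer, well above 1 (e.g. 5 on a weakened 20-level outer edge) to
reproduce the documented failure mode where the detector locks onto the
much brighter inner edge.  A tape-artifact mode adds a bright horizontal
strip near the top.  Suites draw intercepts in 35–55% of the width and
slopes in −1.2…−0.4 columns/row — inside the candidate fan's reach — with
mild monotonicity-preserving curvature.  Everything is deterministic given
the seed.

Phantoms deliberately do **not** model real parenchymal texture, skin
lines, lesions, or scanner-specific artifacts; passing on phantoms
validates the geometry, selection logic and numerics of the pipeline, not
clinical-grade performance on patient data.

## Problem sizes and defaults used in the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline on suites
of 20 noise-free and 20 noisy (noise sd 8, three clutter blobs) 512×512
phantoms — enough to exercise the boundary-geometry randomization while
keeping a full run in seconds.  Observed performance there: 100% detection
rate, ~0.2 px mean boundary column error, FP and FN well under 1%, mean
Hausdorff ≈ 0.4 mm (one pixel).

## Known limitations

- The brighter-inner-layer configuration defeats the intensity tie-break
  by design; on real multi-layer mammograms with weak outer edges the
  detector inherits this failure mode.
- The upward extension above the seed row is a constant column, not an
  extrapolated curve; for seeds found low in the sub-image this
  underestimates the muscle slightly.
- Orientation auto-detection is a brightness heuristic; images with
  bright artifacts in the top-right corner can be flipped incorrectly
  (pass an explicit laterality in that case).
- Boundaries steeper than the candidate fan (losing more than
  `left_bias−1` columns per `K_step` rows) cannot be followed; widen the
  fan via `GrowthParams` for extreme cases.
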