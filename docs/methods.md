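# Methods

`periseg` implements an automated processing chain for periapical
radiographs (PAs): contrast enhancement, adaptive binarization, per-tooth
segmentation by near-vertical separation lines, masking/cropping of
single-tooth tiles, and a small training harness that classifies tiles as
*normal* vs. *furcation lesion*.  Because clinical PAs cannot be shipped
with the package, every stage is exercised against a synthetic phantom
generator with exact ground truth.

## Pipeline model and assumptions

The chain assumes an 8-bit grayscale (or RGB, reduced by ITU-R 601 luma
weights with half-up rounding) radiograph in which three intensity
populations dominate: dark background and interdental spaces, a mid-gray
gingiva/alveolar band, and bright tooth material.  Stages run in this
order:

1. **High-boost enhancement.** The centered spectrum is multiplied by the
   Gaussian high-pass transfer function `H(u,v) = 1 − exp(−D²/(2·D0²))`
   and the real high-frequency component, scaled by a gain `k`
   (`strength`, default 1), is added back to the image.  `H(0,0) = 0`, so
   flat regions are untouched while edges overshoot.  The filter is
   applied on the native image size with the distance grid built from
   `fftfreq`, which is well defined for odd sizes and keeps the transform
   exactly invertible; no padding is performed.  The subtraction-vs-
   addition ambiguity of "removing the filtered noise" is resolved as
   high-boost *addition* (subtracting the high-pass output would blur
   contours); the sign can be flipped through `strength`.
   `D0` defaults to 5% of the image diagonal so the edge emphasis scales
   with image size.
2. **Bright-extreme redistribution.** Pixels above a cutoff (default gray
   170) are linearly remapped into the 30-level band just below it
   (`(cutoff−30, cutoff]`), so specular lighting extremes cannot distort
   the histogram windows that follow.  The band width 30 keeps
   redistributed pixels above typical gingiva levels.  The map is the
   identity below the cutoff and monotone within the remapped segment
   (globally it necessarily jumps downward at the cutoff — that is the
   redistribution).
3. **Adaptive threshold.** From the 256-bin histogram: `Lmax` = modal
   gray in [30, 90] (dark peak), `Rmax` = modal gray in [91, 170] (bright
   peak), `Zmin` = least-populated level in [60, 120] (the valley),
   `Zmid = round((Lmax+Rmax)/2)` as initial threshold.  A threshold `T`
   is accepted iff (a) the valley is near the midpoint, `|Zmin − Zmid| <
   15`, with `Zmin` re-picked in increasing count order when it is not;
   (b) the mass in `[T, 170]` is between 2/3 and 5/6 of all pixels;
   (c) `T ∈ [80, 95]`; and (d) the binarized mean (fraction of pixels
   strictly above `T`) lies in (0.6, 0.85).  Candidates are explored
   outward from `Zmid`, lower level first on ties, so the accepted `T` is
   the qualifying level closest to `Zmid` — which is also how the
   exhaustive-search oracle in the tests defines it.  All window argmax /
   argmin ties resolve to the lower gray level, making the procedure
   bit-deterministic.  Valley re-picks and candidate evaluations both
   count against `max_iter` (default 64); on failure the result is
   flagged unconverged and falls back to Otsu's threshold.  `Zmin` is
   treated as a histogram-count minimum (a valley): a raw intensity
   minimum over [60, 120] would almost always be 60 and carry no
   information.  The stored `zcheck` is evaluated at the *accepted*
   threshold so the reported statistics describe the accepted state.
4. **Segmentation.** Interdental spaces binarize to black, so per-column
   sums of the binary image dip at the gaps.  Projection is per *column*
   (separation lines are near-vertical; row sums would not expose the
   gaps).  Up to `max_lines` (default 5, one PA holds at most five teeth)
   candidate columns are picked greedily from the smallest sums with
   minimum spacing `width//6` ("one tooth distance" for a five-tooth
   frame; ties to the leftmost column).  The pipeline drops candidates
   whose column sum exceeds `gap_sum_fraction` (default 0.35) of the
   median column sum: the greedy picker always returns `max_lines`
   columns, and on frames with fewer teeth the surplus candidates are
   bright columns that would cut through teeth.  Each surviving line's
   two endpoint x-coordinates (row 0 and row H−1) are then shifted
   independently over `[−shift_range, +shift_range]` (default
   `width//10`); the line crossing the fewest white pixels wins, ties
   resolved toward vertical (`|a|+|b|`, then `a`, then `b`).  Both
   endpoints move — a superset of moving either one.  Rasterization is
   half-up rounding of the linear interpolation between endpoints, one
   shared rule for line cost and mask membership, so costs are
   bit-reproducible.
5. **Trimming, expansion, masking.** For each tooth region (consecutive
   line pair; image borders act as virtual vertical lines) the bounding
   lines are first trimmed vertically: each line is replaced by the
   vertical line at its outermost x relative to the tooth, so the kept
   region on the tooth side never shrinks and a tilted line cannot cut
   through the root.  Lines are then pushed outward by
   `floor(width/30)` pixels (error tolerance plus context for the
   classifier), everything outside is set to 0 (black, the radiograph
   background; configurable), and the surviving bounding box is cropped
   into a tile with full provenance.  Membership is inclusive of both
   rasterized boundary columns; a degenerate pair keeps exactly the
   rasterized line column.
6. **Dataset.** Each tile yields 4 variants: original, horizontal flip,
   vertical flip, and "reverse" flip interpreted as the 180° rotation
   (the composition of the other two).  The 7:3 train/validation split is
   decided on *source* tiles before augmentation — flips of a training
   tile can never reach validation — stratified per class by
   largest-remainder apportionment (each class's training share within
   one tile of the ratio).  Only the training split is augmented, the
   shape real radiograph studies use (validation counts stay unexpanded).
7. **Classifier harness.** SGDM (momentum 0.9) with the step schedule
   `lr(e) = lr0 · factor^floor((e−1)/period)` (defaults 1e-4, 0.2, 5),
   mini-batch 32, validation every 3 iterations, max 50 epochs; Adam is
   available as an alternative.  The training log carries epoch,
   iteration, elapsed time, and mini-batch/validation accuracy and loss
   per row.  Inputs are zero-centered (gray − 127.5) but *not* rescaled —
   the image-input convention of mainstream deep-learning toolboxes, and
   the scale the default learning rate is calibrated to.  Backbones are
   pluggable through a registry; heavyweight transfer-learning
   architectures can be registered by the user but are deliberately not
   bundled.  Metrics treat *lesion* as the positive class: accuracy =
   diagonal share, precision = TP/(TP+FP), recall = TP/(TP+FN), F1 =
   harmonic mean.  A zero-denominator metric is reported as undefined
   (None), never 0.  Note that published clinical tables of this
   problem's literature sometimes swap precision/recall labels relative
   to their matrix axes; the formulas above are authoritative here.

### Default backbone

The default `small_cnn` is a two-block convolutional network (3×3 conv →
ReLU → 2×2 max-pool, 8 then 16 channels) whose flattened features are
concatenated with the raw zero-centered input before the linear head — a
wide-and-deep input shortcut — on 32×32 single-channel tiles.  The
shortcut keeps the head's gradient input-conditioned from the first
iteration, which is what makes from-scratch training dependable at the
small default learning rate on a few hundred tiles: across 30 seeded
runs on the phantom tile task the design never finished below 98%
validation accuracy, whereas a plain 4-block stack (still registered as
`cnn4`) converged only for favourable seeds under the same budget.  A
`linear` (logistic-regression) backbone is registered as a sanity
baseline.

## The phantom generator

A phantom renders the three PA intensity targets as flat gray levels:
background 30, interdental gaps 40, gingiva/alveolar band 110, tooth
material 140 (all configurable but ordered `gap < gingiva < tooth`).
Geometry: up to five teeth in equal slots, each a crown with an
elliptical shoulder plus one or two root capsules; interdental gap strips
(5 px wide) run the full height at the slot boundaries; the gingiva band
covers the lower 42% of the frame.  Double-rooted teeth carry a
furcation region between the roots that is filled with bone
(gingiva level) when healthy, or with a dark triangular wedge — apex at
the bifurcation, widening downward, at gap level — when lesioned: the
minimal geometry exhibiting the furcation feature the classifier must
separate.  A global horizontal illumination gradient and additive
Gaussian noise (clipped to [0, 255] and rounded) are applied last;
ground truth (gap columns, per-tooth boxes, labels, root counts) is
recorded before both, so it is exact at any noise level.

The geometry constants were fixed once so that a default phantom's
binary white fraction (teeth + gingiva) sits near 0.70, inside both the
(0.6, 0.85) binarized-mean window and the [2/3, 5/6] check-mass window —
the composition the thresholding method expects of a posterior PA.
Default corpus conditions: width 240–320 px, height 180–240 px, 2–4
teeth, double-root probability 0.5, lesion probability 0.5 on double
roots, noise sd 4, illumination slope ±0.04 gray/px; the noise-sweep
fixture covers sd ∈ {0, 2, 4, 8}.  Every image draws an independent
sub-seed from the master seed, so corpora are exactly reproducible.

What the phantom does *not* emulate: radiographic physics (beam
hardening, scatter), textured bone, overlapping or tilted teeth, crown
restorations, and continuous-tone anatomy.  Passing tests therefore show
that the algorithms implement their contracts exactly and are robust to
additive noise, gradients and geometric variation within the modelled
family — not that clinical accuracy figures transfer.

## Numerical choices

- Half-up rounding everywhere a real value becomes a gray level or a
  column index; numpy's round-half-even is never used on the data path.
- Binarization is strict (`pixel > T` is white).
- `Zcheck`'s interval is closed, `[T, 170]`; the binary-mean window
  (0.6, 0.85) is strictly open, as printed in the method's source tables.
- Line cost ties resolve toward the vertical line; window ties toward
  the lower gray level; split apportionment ties toward the
  lexicographically first class label.
- Degenerate inputs raise: empty histogram windows
  (`DegenerateHistogramError`), single-level images for Otsu /
  iterative-mean, empty masked regions, single-class splits.

## Problem sizes

The test-suite and acceptance-script corpora are sized for a single CPU:
200 default phantoms for the threshold contract, 4 × 50 for the noise
sweep, 80 double-rooted phantoms (~230 tiles) for the classifier run,
10 random 8×8 images for the brute-force DFT oracle, 50–100 random cases
for the line-cost and mask-membership oracles.

## Known limitations

- The adaptive threshold is global per image (as designed); block-wise
  local thresholding is out of scope.
- Teeth are segmented only by near-vertical lines; occlusal
  (horizontal) segmentation and FDI tooth numbering are not attempted.
- The classifier harness demonstrates the pipeline on separable phantom
  tiles; clinical accuracy claims would require clinical data.
- Published expanded-dataset counts in this problem's literature are
  internally inconsistent and are deliberately not reproduced; the
  augmentation factor here is exactly 4.
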