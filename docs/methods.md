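# Methods

`rootseg` implements an end-to-end system for segmenting plant roots from
soil in rhizotron RGB photographs and for turning the segmentations into
the measurements agronomists use. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic test
bed does and does not establish.

## The segmentation model

The segmenter is a U-Net: a five-level convolutional encoder-decoder with
two unpadded ("valid") 3x3 convolutions per level, 2x2 max-pooling on the
descending path, learned 2x2 stride-2 up-convolutions with center-cropped
skip connections on the ascending path, and a final 1x1 convolution — 23
convolutional layers at full depth. Three deliberate deviations from the
classic design: the input layer accepts RGB; every ReLU is followed by
group normalization (8 groups by default) rather than batch normalization,
because batches of 4 tiles give unreliable batch statistics; and there is
no dropout. Weights are He-initialized from a seed.

Because no convolution pads, spatial extent shrinks deterministically: an
input tile of side `s` yields an output of side `s - 184` whenever every
intermediate side stays positive and even before each pooling step (the
valid sides are exactly `s ≡ 12 (mod 16)`, `s ≥ 188`). The native tile is
572x572 in, 388x388 out; each output pixel therefore sees 92 pixels of
context on every side. Full images are segmented by mirror-padding by 92,
tiling the padded image so output regions cover every pixel (edge tiles
shift inward; on overlap the later tile wins), and stitching.

The output head is a single sigmoid-squashed channel: a per-pixel root
probability, binarized at 0.5 for reported metrics. A one-channel sigmoid
head with threshold 0.5 is the simplest head consistent with a Dice loss on
probabilities; a two-channel softmax would be equivalent up to
reparameterization.

The network, its backward pass, and the optimizer are implemented directly
on NumPy arrays: convolutions are lowered to BLAS matrix products (im2col),
and every layer implements its analytic gradient (verified against central
differences in the test suite). `base_channels` scales the channel widths
(64 at full scale; 8 in the desk-scale experiments) without touching the
geometry.

## Loss

Training minimizes, per batch item,

    DL(p, g) = 1 - 2 Σ p_i g_i / (Σ p_i + Σ g_i)         (soft Dice loss)
    L = DL + 0.3 * CE

where CE is the pixel-mean binary cross-entropy and the 0.3 weighting
follows the combination found effective for this task. Dice handles the
class imbalance (root pixels are 0-2.8% of an image); cross-entropy
contributes a well-conditioned per-pixel gradient. Numerical choices: the
Dice term uses soft probabilities during training; probabilities are
clipped to [1e-7, 1 - 1e-7] inside CE; a pair with empty prediction *and*
empty truth has Dice loss 0 (agreement is not penalized); batch reduction
is the mean over items, so gradients are batch-size invariant.

## Instance selection and augmentation

Root pixels are rare, so at the start of every epoch each training image
contributes tiles drawn at random output-region origins (uniform with
replacement, 90 candidates at full scale); candidates whose target region
contains no root pixel are discarded, and the first 40 survivors are kept.
"Contains roots" is judged on the output region, not the input, because
only the output region enters the loss. Validation does the opposite —
every tile in the non-overlapping inference grid is scored, with and
without roots — so validation F1 reflects whole-image performance.

Each selected tile is augmented:

* **Color jitter** with maximum magnitudes 0.3 (brightness), 0.3
  (contrast), 0.2 (saturation), 0.001 (hue). A magnitude `m` means a
  multiplicative factor drawn uniformly from [1-m, 1+m] (hue: an additive
  shift in [-m, m] of the hue circle); the operators apply in the fixed
  order brightness, contrast, saturation, hue.
* **Elastic grid deformation** with probability 0.9. One interpolation
  coefficient γ ~ U[0, 1) couples the elasticity σ = 15 + 45γ (px) and
  intensity α = scale * (200 + 2300γ) with scale ~ U[0.4, 1), so strong
  displacements only occur at high smoothness, which keeps deformations
  realistic. The displacement field is unit-variance Gaussian noise,
  Gaussian-smoothed with σ, scaled by α, and applied identically to image
  (bilinear) and mask (nearest-neighbour, so the mask stays binary);
  out-of-domain samples are filled by reflection, consistent with the
  mirror padding.
* **Normalization** of intensities to [-0.5, +0.5] via v/255 - 0.5.

## Optimization

Plain SGD with Nesterov momentum 0.99, initial learning rate 0.01, weight
decay 1e-5 (applied to all parameters), batch size 4, and a step schedule
multiplying the learning rate by 0.3 every 30 epochs. Adaptive optimizers
are deliberately avoided. The final incomplete mini-batch is kept (small
datasets: every tile counts). After each epoch the pooled validation F1 at
threshold 0.5 is recorded; the weights of the best-validation epoch are the
fitted model (early stopping by checkpoint selection). One master seed fans
out through `numpy.random.SeedSequence` into per-epoch, per-image and
per-augmentation streams; validation computations never touch the weights,
so runs are bit-reproducible and independent of the validation set chosen.

## Data splitting

Images are ranked by annotated root-pixel count (ties broken by id) and
`n_val` evenly spaced ranks — `round(k (N-1) / (n_val-1))`, k = 0..n_val-1 —
go to validation, so both subsets span the full density range. With
`n_val = 1` the median rank is taken. Photographs at the native 4608x2592
size are first cropped to the 3991x1842 analysis region: all surplus
columns from the right edge (image overlap), surplus rows split evenly
between top and bottom (metal frame); the exact offsets are this package's
choice, constrained to those sides.

## The vesselness baseline

The baseline segments by multiscale Frangi vesselness (scikit-image's 2-D
implementation) on the luminance channel, oriented to bright ridges, then a
vesselness threshold and removal of 8-connected components smaller than
`min_component_px` (8-connectivity suits thin diagonal structures).
Its parameters — scale range, the shape-sensitivity β, the
structure-sensitivity c, the threshold, and the component-size floor — are
tuned by CMA-ES minimizing `1 - mean(per-image F1)` over annotated images
(root-free images are excluded, where F1 is undefined). The search runs in
a transformed space (log for strictly positive parameters, logit for the
threshold, log1p for the size floor) to keep CMA-ES well scaled; the scale
count and ridge polarity stay fixed because evolution strategies handle
integer and boolean genes poorly. CMA-ES itself is the standard
(mu/mu_w, lambda) strategy with cumulative step-size adaptation and
rank-one plus rank-mu covariance updates; the incumbent best (including the
starting point, evaluated first) is always returned within the evaluation
budget.

## Quantification

* **Root length**: topological thinning (scikit-image `skeletonize`) of
  the binary mask, then counting the remaining pixels. The count is
  orientation-biased (a 45-degree root of equal Euclidean length yields
  ~30% fewer pixels); this is documented, not corrected.
* **Root intensity** (the manual line-intersect measure): a square grid —
  10, 20, 40 or 80 mm in the reference campaign — is overlaid with its
  origin fixed at the image corner, and crossings per metre of grid line
  are counted. One crossing is a maximal run of foreground pixels along a
  grid line, so a root thicker than one pixel crossing a line counts once,
  and a root running *along* a line also counts once (the ambiguous case
  the manual protocol leaves unspecified). The native scale is
  3991 px / 300 mm ≈ 13.3 px/mm.
* **Agreement** between measures: Spearman rank correlation (with
  p-value) and the r² of a least-squares linear fit on untransformed
  values. Heteroscedasticity in such comparisons is reported
  descriptively, not modelled.

## Synthetic scenes: what they emulate, and what they do not

The generator produces seeded scenes with exact ground truth: low-pass-
filtered noise as spatially correlated soil texture; roots as smoothed
random-walk tubes with per-segment width jitter, brightened strictly inside
the mask; per-root contrast factors in [0.5, 1.3] and a pale (blue-shifted)
channel weighting, so some roots are faint and root color differs from the
brownish soil; optional thin bright scratch artifacts drawn on the image
only (a known false-positive source on acrylic glass); pixel noise; and a
root-pixel fraction controlled to a band defaulting to [0.002, 0.028],
mirroring the 0-2.8% range of real annotations (50 redraw attempts before
a generation error names the unattainable band).

Default scene conditions, chosen once as a realistic desk-scale analogue:
200x200 px scenes, 1-2 roots of width 2-5 px, mean contrast 50, noise SD 6,
two scratches per image in the comparison experiments, and 2 px/mm as the
synthetic pixel scale (a 10 mm grid line every 20 px). The desk-scale
training experiment uses 20 training and 5 validation scenes, a base-8
network, 348-px tiles (164-px outputs), 8 candidate tiles and a 2-tile cap
per image per epoch, and 15 epochs; the density-correlation experiment uses
30 scenes of 320x320 px with 1-4 roots. These sizes are the package's own
desk-scale study conditions; the full-scale defaults (572-px tiles, 64 base
channels, 90/40 instance selection, 73 epochs) remain available.

The scenes do **not** model root branching, occlusion by soil, moisture
gradients, lighting variation across the panel, or temporal growth. Passing
tests on them establishes that the pipeline's machinery is correct and that
the learned segmenter can exploit color and context where a luminance-ridge
baseline cannot; they say nothing quantitative about F1 on real
photographs.

## Degenerate inputs and tie-breaks

* Metrics with zero denominators (precision with no predicted pixels,
  recall and F1 on root-free images) are reported as NaN, never thrown;
  per-image aggregation excludes root-free images.
* Stitching verifies full coverage and reports the first uncovered
  coordinate; overlapped pixels take the last-written tile.
* Max-pool gradient routes ties to the first maximum; padding margins must
  be strictly smaller than the padded side for reflection to be defined.
* All coordinates are 0-based (row, col) from the top-left.

## Known limitations

The NumPy engine is single-threaded BLAS-bound and roughly two orders of
magnitude slower than a GPU framework; full-scale (64-channel, 572-px,
73-epoch) training is out of reach on a laptop CPU, which is exactly why
the desk-scale conditions above exist. Skeleton length inherits the
orientation bias noted above. The Frangi baseline's tuned parameters are
specific to the tuning scenes' scale and polarity.
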