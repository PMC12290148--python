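# Methods

## Problem setting

Planar bone scintigraphy (a gamma-camera acquisition after ^99m^Tc-MDP
injection) maps radiotracer uptake; metastatic bone lesions appear as
compact hot spots whose size varies over more than an order of magnitude
and whose intensity overlaps with benign hot structures (the spine band,
arthritic joints, injection sites). `scintiseg` implements an adversarial
segmentation approach aimed at exactly this multi-scale, low-resolution,
count-noise regime: a U-shaped generator built from dilated-convolution
blocks produces per-pixel lesion probabilities, and a multi-scale critic
supplies a structure-aware training signal beyond the per-pixel
segmentation loss.

## Generator

A five-level encoder-decoder. Channel widths start at `base_channels`
(64 for the full-size model) and double per level; 2x2 average pooling
halves resolution between encoder levels, bilinear interpolation doubles
it between decoder stages.

* **Level 1 — CDC.** Six cascaded units of dilated 3x3 conv + batch norm +
  ReLU with dilation rates 1,2,4,1,2,4 and padding equal to the dilation
  rate (so every block preserves spatial shape). The cycling 1,2,4 schedule
  follows the hybrid-dilated-convolution design rule, which avoids the
  gridding artifact of naive dilation stacks. The cumulative receptive
  field after each unit is 3, 7, 15, 17, 21, 29 pixels, computed by the
  recursion rf_i = ks + (ks-1)(d-1) + s(rf_{i-1} - 1) with rf_0 = 1; the
  test suite verifies the recursion against an empirical gradient-footprint
  oracle (all-positive weights, pass-through norms, backprop from the
  center output pixel) for five dilation schedules.
* **Levels 2–5 — MSFE.** Each multi-scale feature extraction block is a
  CRAC module (the CDC cascade with residual skips from the block input to
  unit 3's output and from unit 4's input to unit 6's output) followed by a
  receptive-field block: three parallel branches of equivalent kernel size
  1, 3 and 5 (1x1; 1x1 then 3x3; 1x1 then two 3x3), each capped by a 3x3
  dilated conv with rates 1, 3, 5, summed with a residual path and the CRAC
  output, then ReLU. Where a skip crosses a channel-count change it becomes
  a 1x1 projection; at equal widths it is an identity (a zero-weight CRAC
  is exactly the identity map, which the tests assert).
* **Image pyramid.** The normalized input average-pooled to 1/2, 1/4 and
  1/8 resolution is channel-concatenated into the inputs of encoder levels
  2, 3 and 4, compensating for information lost to downsampling.
* **Decoder — RMS.** Each of the four stages upsamples, concatenates the
  same-resolution encoder feature (U-Net-style channel concatenation), and
  applies a residual multi-scale block: three dilated conv units (rates
  1,2,4) with a skip carrying unit 1's output to the sum after unit 3.
* **Deep supervision.** The three intermediate stages carry auxiliary
  heads (1x1 conv to one channel, bilinear resize to the input size,
  sigmoid); the final stage's head needs no resize. All four heads emit
  probability maps in [0,1] at input resolution and are supervised jointly;
  with deep supervision disabled only the final head exists.

Inputs must be square-divisible by 2^(levels-1) = 16. Counts are
normalized to [0,1]; the default `per_image_max` divides by the image's own
maximum because tracer uptake varies strongly between patients, so a fixed
1/65535 scale (also provided) would compress most images into a tiny range.
Convolutions use Kaiming fan-in initialization; the model seed defaults
to 42.

## Critic and adversarial objective

The critic consumes the elementwise product of the normalized image with a
mask (predicted probabilities or binary ground truth) — alternatives
(2-channel concat, sum, mask only) are provided as configuration. It stacks
4x4 stride-2 convolutions (leaky ReLU 0.2; batch norm except in the first
stage; channels base, 2x, 4x, then capped at 8x). Instead of a scalar
real/fake probability — which gives weak, unstable gradients — every
stage's feature map is flattened, scaled by `layer_weight / element_count`,
and concatenated into a signature vector. The adversarial distance between
two inputs is the L1 norm of the signature difference divided by the number
of stages: with unit weights, the average over scales of the per-scale mean
absolute feature difference. The per-element and per-stage normalization
keeps the distance of [0,1]-valued inputs well below 1.

The generator's adversarial loss is the mean over heads of the distance
between the signature of (head x image) and (gt x image); the critic
minimizes one minus that quantity on detached generator outputs, so the two
objectives sum to exactly 1 on any fixed inputs (asserted to machine
precision in the tests). The total generator objective is
`alpha * L_seg + beta * L_adv` with alpha = beta = 1 by default.

## Segmentation loss and metrics

The segmentation loss is the head-weight-normalized mean of (1 - soft
Dice), with soft Dice = (2 sum(p g) + s) / (sum p + sum g + s) and
smoothing s = 1 to keep empty masks well-defined; binary cross-entropy and
Dice+BCE variants are available. On binarized inputs soft Dice equals
2TP/(2TP+FP+FN), the harmonic combination of precision TP/(TP+FP) and
recall TP/(TP+FN); the equality is tested against a pixel-count oracle.
Evaluation binarizes the final head at >= 0.5 (a pixel at exactly 0.5 is
foreground), scores each image separately, and macro-averages over the test
set; whether to macro- or micro-average is an open convention and macro was
chosen because per-image scoring matches per-patient reporting. An image
with empty ground truth and empty prediction scores 1 (a correct
rejection); this is configurable. Repeated runs are reported as mean +/-
standard deviation.

## Training

Alternating Adam updates (one critic step per generator step; the same
learning rate for both networks; no decay, early stopping or
augmentation — hooks exist in the config but the defaults are plain).
Full-size defaults: learning rate 1e-4, batch size 32, 600 epochs, seed 42,
five repeated runs with seeds seed + run_index. Train/test splitting is by
patient, never by image: both views of a patient stay on the same side, so
near-duplicate anatomy cannot leak across the boundary (asserted over 100
random seeds).

## Synthetic phantoms

No public scintigram corpus exists, so the package ships a phantom
generator that reproduces the statistical structure the method assumes:

* a uniform background rate plus a bright vertical spine band (width
  image_size/8) — additive Poisson rates of 20, +60 counts by default;
* 1–3 axis-aligned elliptical lesions per image (+120 counts), radii drawn
  from a small (1.5–3 px) or large (4–8 px at 64 px frame) range with equal
  probability, eccentricity uniform in [0.5, 1]; with probability 0.2 the
  lesions of an image cluster, their centers constrained to lie within one
  cluster diameter (twice the maximal large radius);
* benign confounders (0–2 per image) that share the lesion intensity range
  but sit at peripheral sites (within a couple of pixels of the frame edge,
  emulating shoulder joints, injection sites and tracer pooling), and never
  intersect the lesion mask — the positional cue is what a segmenter must
  learn, since intensity alone cannot separate them;
* independent Poisson noise per pixel (gamma-camera counts are
  Poisson-like); the posterior view mirrors the anterior rate map with
  fresh noise.

The mask is exactly the union of the lesion ellipse supports. What the
phantom does **not** model: skeletal anatomy beyond the spine band,
attenuation and scatter physics, detector blur, and the long-tailed
inter-patient uptake variation of real cohorts. Passing the phantom-based
tests therefore demonstrates that the architecture, losses and training
loop work as specified — not that clinical accuracy would be reproduced.

## Problem sizes used in the automated checks

The package's neural-network engine is a self-contained numpy
implementation (reverse-mode autodiff with im2col convolutions), so the
test suite exercises training at desk scale: the miniature recovery study
uses 32-px phantoms (radii scaled to the frame: small 1–2 px, large
2.5–5 px), 26 synthetic patients split 20/6 by patient (40 training and 12
held-out images), generator base width 8, a 3-stage critic of base width 8,
batch size 8, and 60 epochs at learning rate 1e-3 (scaled up from the
full-size 1e-4 to match the roughly tenfold-shorter schedule). Five
adversarial runs (seeds 42–46) must reach a held-out mean DSC above 0.5,
and their run-to-run prediction consistency (per-run deviation of held-out
DSC from the group mean) is compared pairwise against five seg-loss-only
baseline runs — the adversarial term is expected to damp run-to-run
variability of the final model, not to smooth the training curves
themselves. Structural tests run single
forward passes up to 256 px. These sizes are the package's chosen test
conditions; the full-size defaults above remain the recommended settings
for real training.

## Numerical choices

* float32 throughout; single-threaded numpy makes runs bit-reproducible
  for fixed seeds (asserted on epoch-level loss traces).
* Soft-Dice smoothing 1.0; BCE probabilities clipped to [1e-7, 1 - 1e-7].
* Batch-norm eps 1e-5, momentum 0.1; "pass-through" mode used by the
  receptive-field tests simply omits the norm layer.
* Bilinear resize uses half-pixel centers (align_corners = false); its
  backward pass is the exact transpose of the forward interpolation matrix.
* Poisson counts are clipped to the 16-bit ceiling (unreachable at default
  rates) before casting to uint16.
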