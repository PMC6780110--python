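# Methods

## Model

The segmentation network is a fixed-depth encoder–decoder: four encoder
convolution blocks (widths 64, 128, 256, 512 at the reference scale), a
mirrored decoder, and a final 3×3 convolution with one filter per class
followed by per-pixel softmax. Every convolution is followed by batch
normalization; counting per-channel scale and shift (2 parameters/channel)
reproduces the reference parameter table exactly. Two residual streams run
through the network:

* **Inner projection paths** (six, 1×1 conv + BN): in all blocks except the
  first encoder and last decoder block, the block input is projected to the
  block's output width and added to the second convolution's BN output
  before the block's closing ReLU — `Y = S + F` on the encoder side,
  `Z = S′ + F` on the decoder side.
* **Outer identity paths** (four): the activation after the first ReLU of
  encoder block *i* is added, unchanged, to the activation after the first
  ReLU of decoder block *i* (`T′ = K + T`). Because the shapes must agree
  exactly, the decoder's first convolution keeps the block width and the
  *second* convolution performs the width reduction.

Downsampling is 2×2/stride-2 max pooling with floor division; each pooling
stage records its argmax indices and pre-pool shape, and the paired
unpooling stage scatters values back to those positions, so odd sizes
(447→223→111→55→27) round-trip exactly. Positions dropped by floor
division return as zeros, matching their zero gradient.

### Numerical and structural choices

* 3×3 convolutions use symmetric single-pixel zero padding, stride 1 — the
  only choice that reproduces the published shape schedule.
* ReLU is placed immediately after each residual add and before
  pool/unpool. Max pooling and ReLU commute (`max∘ReLU ≡ ReLU∘max`,
  asserted numerically in the tests), so this is equivalent to the
  pool-before-activation reading of the reference table.
* The projection branch takes the *block input* (post-pool on the encoder
  side, post-unpool on the decoder side).
* Argmax ties in prediction assign the background class — conservative for
  screening, where spurious vessel growth would trigger referral.
* Weight init is He-style (std √(2/fan-in)) for convolutions, scale 1 /
  shift 0 for BN, from a seeded generator; the published training left the
  scheme open. BN running statistics (momentum 0.1) are used at inference
  and are not counted as trainable parameters.
* The engine is float32 NumPy: convolution by im2col + matrix multiply,
  hand-written reverse-mode gradients for every op. Correctness is checked
  against a naive per-pixel reference forward pass (≤1e-5 relative error on
  16×16 inputs) and float64 central-difference gradient checks.

## Training recipe

Adam (β₁ 0.9, β₂ 0.999, ε 1e-6 in the update denominator), constant
learning rate 5e-4, mini-batch 7 with partial final batches dropped,
15 epochs with per-epoch reshuffling, gradient clipping by global L2 norm
(threshold 1.0 by default; unstated in the source recipe and largely inert
under Adam's per-parameter normalization). The loss is per-pixel
cross-entropy weighted by median-frequency class balancing, with the
per-class frequency denominator counting only the images in which the
class occurs; weights are computed once from the training masks. Images
enter the network as raw RGB scaled to [0, 1] — no other preprocessing, by
design of the method.

## Augmentation

Three deterministic stages applied identically to image and mask with
nearest-neighbor resampling (masks stay strictly binary): (1) horizontal
and vertical flips, n → 3n; (2) three fixed translate-crop-resize recipes
(+10/−10 no-flip, +15/+15 vertical, +20/−20 horizontal) applied
*recursively* — each recipe doubles the accumulated set, 3n → 24n; (3)
three further recipes (−10/+10, −15/+15 vertical, −20/+20 horizontal)
applied independently, adding 72n. The training set is stage 2 ∪ stage 3 =
96n, so 20 sources give exactly 1920. Sign convention: +dx shifts content
toward larger columns, +dy toward larger rows; flips are applied before
translation. The stage-1 set survives inside stage 2 and is not added
again. (Note: at batch 7, 15 epochs over 1440 images gives 3075 iterations
— the published iteration count matches the stage-3 set size rather than
the full 1920; the expansion arithmetic above is the one consistent with
all the printed cardinalities.)

## Synthetic fundus data

The generator emulates only the properties of fundus photographs that the
pipeline depends on: a dark reddish, mildly textured circular field of
view on a black frame; thin, low-contrast, curvilinear branching vessels
(biased random walks with heading noise, stochastic branching, and width
taper, stamped as disks); and a vessel fraction held in a 5–15% band
(bracketing the ~9:1 background:vessel ratio of real 447×447 masks) by
sprouting stems until mid-band and retrying out-of-band attempts with
derived sub-seeds. Everything is deterministic under the master seed, with
disjoint per-pair sub-seeds.

It does **not** model optic disc, fovea, lesions, interlaced capillary
texture, camera vignetting, or inter-image illumination variation.
Passing the synthetic end-to-end check therefore shows that the
architecture, gradients, balancing, and evaluation plumbing work and that
the network can learn a low-contrast curvilinear class from few examples —
it says nothing about clinical-grade performance on real fundus
photographs, which requires the public benchmark datasets and
full-resolution training far beyond a single-CPU run.

## Scaled-down end-to-end run

The reference-scale network (447×447, base width 64, ~9.7M parameters)
is not trainable in minutes on one CPU, so the end-to-end property check
uses the same topology at 128×128 with base width 16, trained on the
flip-expanded set of 24 synthetic source pairs (72 images → 150 optimizer
steps under the standard schedule) and evaluated on 8 held-out pairs. The
flip stage stands in for the full 96× expansion, which at this image size
would multiply the run into hours without changing what the check
demonstrates; the schedule itself (optimizer, learning rate, batch size,
epochs, balancing) is untouched. Under seed 7 this run reaches pooled
accuracy 0.92 and sensitivity 0.99 on the held-out pairs with
monotonically decreasing epoch loss; the accuracy floor of the acceptance
check (0.90) also exceeds what a constant-background predictor achieves
(~0.89 at the generator's vessel fraction).

## Evaluation conventions

Metrics are computed over all image pixels by default; an optional binary
evaluation region (e.g. the circular field of view) is supported because
conventions differ across the retinal literature. AUC pools pixels across
a dataset by default (per-image values are also reported). Zero
denominators yield NaN rather than an exception in reports. Overlay
rendering paints tp/fp/fn in configurable colors (blue/green/black by
default; red for misses is a common alternative) over a dimmed grayscale
background remapped into [32, 159] so no background pixel can collide with
an error color — recounting painted pixels reproduces the confusion counts
exactly.

## Screening rule

The visit-to-visit comparison uses relative vessel-pixel change
`(curr − prev)/prev` with a single tunable threshold, default 5%. The
threshold is a documented placeholder, not a clinically validated cut-off;
registration between visits is assumed done upstream. Whole-image pixel
counts are used (not field-of-view-normalized), matching how the reference
counts were reported.

## Known limitations

* BN uses mini-batch statistics during training; with batch 7 the
  estimates are noisy, which mildly regularizes but makes very small
  batches inadvisable.
* The im2col engine favors clarity over memory: training the reference
  447×447 configuration is out of scope for this implementation.
* `compare_visits` requires a nonzero previous vessel count and identical
  pixel grids; cross-resolution comparison is intentionally not supported.
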