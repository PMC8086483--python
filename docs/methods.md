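# Methods

## Problem setting

Two imaging routes produce RGB images of the same tissue with very
different contrast.  Non-linear multimodal (NLM) microscopy packs CARS,
TPEF and SHG signals into the red, green and blue channels (pixel size
0.227 µm); conventional H&E histology stains nuclei dark purple and
cytoplasm/stroma pink (digitized at 0.219 µm).  Structures that are
signal-bright in NLM (lipid-rich epithelium, collagen) are typically
stain-dark in H&E — an inverse-contrast relationship.  The package learns
the translation NLM → H&E as an image-to-image mapping on 256×256 patches
scaled to [−1, 1].

## Pre-processing

The two modalities follow strictly separated routes, enforced by the API:

* **H&E**: grayscale conversion (ITU-R BT.601 luma 0.299/0.587/0.114 — a
  documented choice, the conversion is otherwise unconstrained) and
  contrast inversion `v → 255 − v` are applied *only* to build the moving
  image for registration; the model always sees the untouched H&E pixels.
* **NLM**: per-channel 3×3 median filter → ×4 block-mean downsampling →
  illumination flattening (division by a Gaussian-blurred copy, σ = 50 px,
  renormalized to the channel mean) → 1st–99th-percentile contrast stretch.
  Contrast inversion of the NLM image is applied *only* when preparing
  generator inputs for training/inference.  The kernel, σ and percentiles
  are exposed in `PreprocessConfig`; a flat channel passes the stretch
  unchanged.

Registration (supervised route only) estimates a similarity transform
(translation, rotation, isotropic scale) by maximizing Mattes mutual
information (32 bins, full sampling for determinism) over a 3-level
multi-resolution pyramid (shrink 4/2/1, smoothing 2/1/0), via SimpleITK.
The default optimizer is regular-step gradient descent (lr 1.0, min step
1e-4, ≤200 iterations, relaxation 0.6).  A gradient-free 1+1 evolutionary
optimizer — the classic multimodal-toolbox default — is available in
`RegistrationConfig`, but on the phantom benchmark it consistently leaves
the rotation parameter at its initial value while costing an order of
magnitude more time, so it is not the default.  Results are reported as the
*correction* applied to the moving content, in (row, col) pixel
coordinates; warped-out-of-support pixels are zero-filled and recorded in a
mask.  A precomputed transform can be supplied instead of estimation.

Patch handling: images are tiled into size-256 (reduced profile: 64)
squares on a stride equal to the size, with bottom/right reflection padding
so stitching is an exact inverse on the original support; origins are
0-based (row, col).  Supervised pairs are dropped if the H&E patch touches
any zero-filled registration pixel (strictest reading — one pixel
disqualifies).  Background patches are dropped when their *homogeneity
factor* — the fraction of grayscale pixels within ±10 of the patch median —
exceeds 0.60.  The factor definition is this package's documented stand-in
for an unspecified published criterion; tolerance and threshold are
configurable.  Scaling to the model range is `v → v/127.5 − 1`, inverted by
round-half-even back to uint8 (exact on all 256 values).

## Architectures

All networks operate on single samples in (C, H, W) float32; convolutions
use TF-style `same` zero padding; transposed convolutions are implemented
as the exact adjoint of the corresponding strided convolution.
"Batch normalization" with the batch size of one used throughout equals
per-sample spatial (instance) normalization; one implementation serves both
network families and always uses current statistics.

* **U-Net generator** (paired route): 8 encoder blocks (conv k4/s2 →
  norm → LeakyReLU 0.2) with 64, 128, 256, 512, 512, 512, 512, 512 filters;
  no norm on the first block and on the 1×1 bottleneck.  7 decoder blocks
  (transposed conv k4/s2 → norm → 50% dropout → ReLU) mirroring the encoder
  filters, each concatenated with its encoder skip (post-concat channel
  sequence 1024, 1024, 1024, 1024, 512, 256, 128; no norm on the first
  decoder block), then a transposed-conv output layer to 3 channels with
  tanh.  The norm-free block placement follows canonical practice where the
  published description is ambiguous.
* **PatchGAN discriminator**: convs k4 with 64, 128, 256, 512 filters and
  LeakyReLU 0.2, then a 1-channel k4/s1 conv with sigmoid.  The published
  contract is internally inconsistent — a 16×16 map on a 256×256 input
  requires four stride-2 layers (receptive field 94), while the stated
  70×70 receptive field requires strides (2,2,2,1) (map 32×32).  Both
  variants are provided; `paper_strides` (16×16 map) is the default, `rf70`
  honors the canonical 70-pixel field.  The map is aggregated to a single
  probability by its arithmetic mean.  The receptive-field recursion
  `r ← (r−1)·s + k` is verified by a gradient-footprint probe with norm
  statistics frozen (their spatial coupling would otherwise hide the
  convolutional footprint).
* **ResNet generators** (unpaired route): c7s1-64, d128, d256, six
  residual blocks (two k3 convs with instance norm, additive identity),
  u128, u64, c7s1-3 with tanh.

Weights are initialized N(0, 0.02²) (norm gains N(1, 0.02²), biases 0)
from a seeded generator; identical seeds give bit-identical networks.

## Training

Adam (lr 2·10⁻⁴, β₁ 0.5), batch size 1, data order reshuffled per epoch
from the run seed, alternating discriminator-then-generator updates whose
gradients are never shared; generator checkpoints every 5th epoch (the
published schedule: 100 epochs, 20 checkpoints).  The discriminator loss is
halved before each update to slow it down; by default this applies to the
cycle model's discriminators too (configurable).  The least-squares
adversarial form is the default for both routes; binary cross-entropy is a
config option for the paired discriminator.  The cycle objective implements
adversarial (G1 only by default — the second generator's adversarial and
identity terms are optional flags, off to match the published objective),
identity (G1 on H&E), and forward/backward cycle terms with weights
1 : 5 : 10 : 10.  Non-finite losses abort with a diagnostic record.
Checkpoint selection is automated: best mean validation SSIM (or CSS, or
lowest MSE), ties broken toward the later epoch — replacing visual
inspection of saved models.

The **reduced profile** (`TrainConfig.reduced()` /
`GeneratorSpec*.reduced()`) divides all filter counts by 8 and works on
64×64 patches with a 6-deep U-Net; every architectural rule is otherwise
identical.  The test suite trains it for 6 epochs on 200 phantom pairs
(supervised recovery) and 5 epochs on 48-patch pools (unpaired
cycle-improvement), sizes chosen so ten seeded CPU runs complete in
minutes; the supervised criterion is comfortably met well before the
20-epoch bound.

## Inference

Whole images are contrast-inverted, tiled, predicted patch-wise, unscaled
to 8-bit and stitched at the recorded origins (padding trimmed).  The
visible seam at every patch-size-th row/column is repaired by replacing
each seam pixel with the value at the seam position of a least-squares line
through its three nearest neighbours on each side, perpendicular to the
seam — with symmetric offsets this equals the six-neighbour mean; a
two-neighbour variant is available.  Row seams are processed before column
seams; output is clipped to [0, 255] with round-half-even, and a second
application changes no pixel by more than one count.  An optional
post-hoc contrast reduction scales each channel about its mean
(`v → μ + f·(v − μ)`, default factor 0.7 where requested).

## Evaluation

* **MSE** on the 0–255 scale over evaluated pixels and channels (consistent
  with reported magnitudes of order 10³).
* **SSIM** per channel, averaged.  Default `local` mode: 11×11 Gaussian
  window, σ 1.5, c₁ = (0.01·255)², c₂ = (0.03·255)², population
  covariance (scikit-image).  `global` mode evaluates the closed formula
  once with whole-image statistics and is the literal printed definition.
* **CSS**: images → CIELAB (sRGB companding, D65, 2° observer); for each of
  A*/B*, per-pixel `Sim = 1 − |Δ| / max|Δ|`, kept only where `Sim > 0.5`,
  averaged; channel scores averaged with equal weight.  `max|Δ|` is the
  per-image-pair, per-channel maximum (so a zero-difference channel scores
  1); a fixed theoretical denominator is a config alternative, and is the
  convention under which CSS is monotone in any single pixel's distance.
* **Background exclusion** reuses the homogeneity criterion tile-wise
  (256×256 by default); the mask derived from the reference image is shared
  by all three metrics so means cover the same pixel set.

## Phantom generator

The phantom draws a label map — elliptical crypts (pale lumen inside a dark
epithelial ring), stroma textured by a Gaussian-smoothed multiplicative
field (σ 8 px, amplitude 0.18, strong enough that tissue tiles read as
heterogeneous under the homogeneity criterion), sparse dark nuclei,
optional blank background quadrant — and renders it twice: H&E palette
(pale-pink lumen, dark-purple epithelium, pink stroma) and NLM channel
intensities (signal-bright epithelium, SHG-rich stroma, signal-dark nuclei
and lumen), deliberately in inverse contrast.  Additive Gaussian noise
(σ = 4 counts by default, clipped) is applied per channel.  Both renderings
derive from one label map, so a perfect translation oracle exists, and
misalignments (shift/rotation/scale about the center) are injected with an
exactly recorded 3×3 ground-truth transform.  Everything is deterministic
per seed.

The phantom exercises the pipeline's geometry, contrast relationship and
filtering rules; it does **not** model optical physics, stain variability,
focal-plane mismatch between modalities, or disease-dependent tissue
alteration.  Passing phantom benchmarks therefore demonstrates pipeline and
optimization correctness, not clinical staining quality — the reported
clinical-scale figures require real tissue data and full-scale training,
both outside this package's test scope.

## Numerical choices and limitations

* float32 network arithmetic; float64 for metrics and image post-processing.
* Reflection padding for tiling (edge padding only for degenerate inputs
  smaller than the pad); training-set patches that are more than 50%
  padding can be dropped via `padding_fractions`.
* Checkpoints are saved as `.npz` plus a JSON manifest (epoch, spec, seed);
  the pipeline runner writes a run manifest with per-stage seeds (fanned
  out from one top-level seed by hashing), timings and output checksums,
  and can resume completed stages.
* Single-sample (batch-1) training only, matching the published schedule;
  no learning-rate schedules, replay buffers or perceptual losses.
* The numpy implementation is CPU-bound: full-scale 256×256 training is
  functional but slow; the reduced profile is the intended test vehicle.
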