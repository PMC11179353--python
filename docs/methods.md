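# Methods

## Overview

`growsim` implements a two-stage, image-based crop-growth simulation
framework. Stage one is a multi-conditional Wasserstein GAN with
gradient penalty (CWGAN-GP) that generates an image of a plant stand at
an arbitrary target growth stage from (i) an input image of the same
stand at some acquisition time, (ii) conditions describing the input
image, and (iii) conditions describing the image to generate. Stage two
is a growth-estimation module that derives plant traits — projected
leaf area (PLA) and per-species dried biomass (BM) — from real or
generated images, so that generations can be judged by the traits they
imply rather than only by pixel similarity.

Conditions come in three types and any subset containing time forms a
valid *condition signature*:

- `t` — discrete acquisition time (days after sowing), embedded by a
  sinusoidal positional encoding (base 10 000, length 64) followed by a
  two-layer MLP with SiLU;
- `c` — categorical treatment id (mixture composition × sowing
  density), embedded by a lookup table;
- `b` — continuous per-species biomass vector (spring wheat SW, faba
  bean FB; t/ha), standardized by training-set mean/scale and embedded
  by a two-layer MLP with SiLU.

Within one embedding family all per-condition embeddings share a common
width (64 in the generator family Φ, 256 in the critic family Ψ) so no
condition is weighted a priori; for the same reason the lookup table is
initialized at a scale comparable to the MLP embeddings' output scale
(σ = 0.3), so no condition type dominates the concatenation at init.
Present embeddings are concatenated in the fixed order (t, c, b). Φ and
Ψ share architecture but never weights.

## Generator

The generator is an encoder–decoder. The encoder is a residual network
with stride product 32 (so 256 px inputs give an 8×8 latent map with
8×width channels; the full-scale width 64 gives the 512-channel
bottleneck). Every batch-normalization layer is replaced by
*conditional batch normalization* (CBN): after normalizing with batch
statistics, the per-channel scale `1 + γ(a)` and shift `β(a)` are
linear projections of the concatenated condition embedding `a` — the
input-side embedding `a_in` throughout the encoder, the target-side
embedding `a_gen` throughout the decoder. Projections are drawn with
small (σ = 0.02) weights around the identity affine so training starts
near plain batch normalization.

Stochasticity enters through a 128-d standard-normal noise vector `z`
mapped by a three-layer linear network (SiLU in between, widths
geometrically interpolated) to a latent code `w` matching the
bottleneck channel count; `w` is broadcast over the spatial grid and
added to the latent map after the final encoder block. The decoder
mirrors the encoder with nearest-neighbor ×2 upsampling followed by
residual blocks (avoids checkerboard artifacts), and ends in a tanh so
outputs live in [−1, 1]; images are mapped between [0, 1] storage range
and model range by explicit helpers.

Design choices the architecture leaves open and how they were fixed:

- `w` is added after the last encoder block (before any decoder
  computation); adding before the final activation is equally
  plausible and untested.
- The decoder upsamples with nearest + conv.
- Output activation tanh.

## Critic

The critic scores a (candidate, input) image pair under the conditions
of both sides. The two images are concatenated channel-wise (6
channels), passed through a conv + LeakyReLU(0.2) stem and
conv/instance-norm/LeakyReLU blocks (stride 2) until the feature map is
16×16. Batch normalization is avoided entirely (it couples the batch
and breaks the per-sample gradient penalty); instance normalization
carries no learnable affine. Every condition of `y_in` and `y_gen` is
embedded to 256 dimensions by Ψ, reshaped to a 16×16 plane and
concatenated to the 16×16 feature map (intermediate fusion). Two more
stride-2 blocks, a 1-channel conv and a spatial mean produce the
unbounded scalar score.

## Objective and training

The critic maximizes `E[D(X_ref, X_in, y)] − E[D(X_gen, X_in, y)]`
minus a gradient penalty; the generator maximizes
`E[D(X_gen, X_in, y)]`. The penalty blends reference and generated
images per batch element, `X̂ = ε X_ref + (1−ε) X_gen` with
ε ~ U[0, 1], and penalizes `λ_GP (‖∇_X̂ D‖₂ − 1)²` with the norm taken
over all pixels and channels; gradients are taken w.r.t. `X̂` only,
with the input image and conditions held fixed (the conditions are
passed to the critic inside the penalty forward pass). λ_GP defaults to
10 and the critic takes 5 steps per generator step; both values follow
common WGAN-GP practice. Optimization is Adam, lr 1e-4, betas (0, 0.9).
The penalty's norm carries a 1e-12 stabilizer inside the square root,
which bounds the error of the zero-gradient corner case at ~2e-6 of
λ_GP.

Pair sampling iterates over all training images as inputs once per
epoch and draws the reference uniformly from the other images of the
same sequence; treatment never changes within a sequence, so
c_in = c_gen during training. Augmentations — horizontal/vertical
flips, 90° rotations, slight translations, and ShadowOut (a
semi-transparent CutOut: a random rectangle multiplied by an opacity
α < 1) — are applied with one draw to both images of a pair. Model
selection takes the epoch with the lowest validation perceptual
distance. All randomness (init, data order, augmentation, noise,
blending) derives from one seed.

At inference any condition combination matching the signature is
accepted: the treatment may change between encoding and decoding, the
biomass may be rescaled freely, and times outside the training range
are allowed (the positional encoding is defined for all integers).

### Desk-scale training configuration

The full-scale configuration (width 64, 256 px, batch 64, 5000 epochs)
is expressed by the same code but is a multi-week GPU workload. The
test suite instead trains a width-16 model on 32×32 synthetic images
(64 sequences, 8 dates), where the whole run must fit in minutes of CPU
time — two to three orders of magnitude fewer generator updates than
the full-scale schedule. Under a purely adversarial objective that
budget leaves the generator far from the growth-tracking regime, so the
desk-scale configuration enables a paired-L1 reconstruction term
(`recon_weight` in `TrainConfig`, default 0 = pure objective, as in the
full-scale setup) and a learning rate of 3e-4. The L1 term is the
standard stabilizer of paired image-to-image GANs; it is reported here
as a property of the desk-scale test configuration, not of the method.
λ_GP = 10 and n_critic = 5 are unchanged.

## Growth estimation

*Segmentation and PLA.* On synthetic data, plants are segmented either
from stored ground-truth masks or by a hue threshold: vegetation is
`g > 1.05 r + 0.02 and g > b` (ratio form keeps the gate stable under
the global brightness jitter), split into species by hue windows
(spring wheat 36°–108°, faba bean 108°–216°). A pluggable `external`
slot accepts any callable producing masks, which is where a fine-tuned
instance-segmentation model plugs in for real data. PLA is the mask
pixel sum, also reported as % of image and as physical area via the
squared ground sample distance; optionally restricted to the connected
component nearest the image center (ties break to the lowest label
index). The center-instance percent is computed from that instance's
mask alone.

*Biomass regression.* A small CNN with a two-output ReLU head (biomass
cannot be negative) is trained with MSE against the growth-curve
reference values, mirroring the full-scale two-output regressor
contract with a width-configurable backbone. Trait deviations between
generated and reference images are summarized by MAE and ME
(`ME = mean(PT_gen − PT_ref)`; negative = underestimation), with
`|ME| ≤ MAE` by construction.

## Image-quality evaluation

- **MS-SSIM** (optimum 1) follows the multi-scale construction:
  contrast/structure terms at each scale of a dyadic pyramid, luminance
  at the coarsest, standard weights (0.0448, 0.2856, 0.3001, 0.2363,
  0.1333) renormalized when fewer scales fit; an 11-pixel Gaussian
  window (σ = 1.5); channels averaged. Images smaller than the
  requested pyramid raise an error naming the feasible scale count, and
  the default picks the largest feasible pyramid (2 scales at 32 px).
- **Perceptual distance** (optimum 0) follows the LPIPS construction —
  channel-unit-normalized activations compared layer-wise, spatially
  averaged, summed over layers — behind a pluggable extractor. The
  desk-scale extractor is a fixed-seed random-weight CNN; identity,
  symmetry and non-negativity hold for any extractor, so the test
  surface needs no pretrained weights. Adapters for pretrained
  perceptual backbones implement the same interface at full scale.
- **FID** (optimum 0) is the Fréchet distance between Gaussian fits of
  two feature sets: `‖μ_a−μ_b‖² + Tr(Σ_a+Σ_b−2(Σ_aΣ_b)^{1/2})`,
  unbiased covariances with a 1e-6 diagonal regularizer. Features are
  pooled over the whole evaluation split (not per time point).
- **Δt strata**: every prediction pair falls in exactly one of
  T0 (|Δt| = 0), ST (1 ≤ |Δt| ≤ 10), LT (|Δt| ≥ 11). Empty strata are
  reported as absent, never as zero.
- **Variability images**: the per-pixel standard deviation over n = 10
  generations with different noise, averaged over channels and
  overdrawn ×4 for display. No monotone relation between |Δt| and
  variability is asserted — conditional GANs are known to be
  overconfident at long horizons.

## Synthetic crop-mixture testbed

The synthetic module emulates the statistical structure of a real
two-species mixture trial:

- **Factorial design** — `f` faba-bean cultivars × `s` spring-wheat
  entries as 1:1 mixtures plus all monocultures, crossed with `d`
  sowing densities: `(f·s + f + s)·d` treatments (defaults 2, 12, 2 →
  76). Replication: 4 plots per treatment, 8 for FB monocultures
  (default design → 320 plots); each plot yields 7 independent image
  clippings (sequences). How clippings relate spatially is not modeled;
  they share the plot's treatment and are treated as independent
  sequences.
- **Growth curves** — per-species logistic `K/(1+exp(−r(t−t0)))` in
  t/ha with multiplicative modifiers: density 0.8× (low) / 1.2× (high)
  of the asymptote, mirroring sowing at 80%/120% of sole-crop density,
  and ±15% cultivar factors drawn once per design. Defaults (SW: K 6,
  r 0.11/d, t0 55 d; FB: K 4, r 0.10/d, t0 60 d) give realistic
  mid-season inflection and end-of-season magnitudes for a cereal /
  legume mixture. The curves stand in for a process-based crop model's
  daily biomass output: they are monotone in time and separable by
  treatment, which is all the conditioning pathway consumes.
- **Renderer** — spring wheat as thin row-structured rectangles, faba
  bean as blobs, over noisy soil; element positions are fixed per
  sequence and element sizes grow monotonically with biomass, with
  canopy cover rising from ~0 % pre-emergence to ~20 % late season at
  32 px (higher at larger rasters). The two species use separated hue
  ranges (yellow-green vs blue-green) so the hue segmenter can recover
  ground truth (IoU ≥ 0.95 at early/mid stages); overlap is allowed
  late. A per-date brightness/tint jitter shared by all plots of one
  date emulates varying illumination between flights; an optional
  alignment-jitter flag emulates registration error.
- **Splits** — entire sequences are assigned to train/val/test
  (spatially separated splits); fractions are honored exactly by
  rounding (0.7/0.15/0.15 on 20 sequences → 14/3/3).

What the testbed does *not* emulate: 3-D canopy structure, weather
coupling, radiometric realism, weeds, within-treatment soil
heterogeneity. Passing tests therefore show that the architecture,
objective, conditioning pathway and evaluation stack are implemented
correctly and can learn treatment- and time-conditioned appearance at
desk scale — not that the model reaches field-data quality.

## Numerical choices and degenerate inputs

- Single-precision tensors by default; double-precision inputs are
  preserved through the graph, so closed-form checks run at full
  precision.
- CBN with batch size 1 in training mode warns (degenerate statistics);
  instance norm and eval-mode CBN are batch-size-independent.
- FID on near-singular covariances relies on the 1e-6 ridge; `sqrtm`'s
  spurious imaginary parts are discarded.
- Empty evaluation strata are reported as absent; MAE/ME require at
  least one pair; out-of-vocabulary treatment ids raise (no silent
  clipping).
- Checkpoints round-trip weights and the full architecture manifest;
  a loaded model reproduces generations bit-exactly.

## Problem sizes used by the test suite

Unit tests run width-4/8 models on 32 px images. The end-to-end test
trains the width-16, 32 px configuration on 64 sequences for a fixed
number of epochs chosen so the suite completes comfortably on one CPU;
the acceptance script recomputes the analytic metric identities on
freshly generated 256 px inputs and 1000×64 feature sets in seconds.

## Known limitations

- The desk-scale end-to-end behavior is demonstrated with the L1
  stabilizer; pure-adversarial convergence is out of desk-scale reach
  by design (the full-scale schedule is ~3 orders of magnitude longer).
- The 32 px configuration has a 1×1 spatial bottleneck, so positional
  detail survives mainly through decoder conditioning; generated
  low-level texture is soft.
- The hue segmenter is specific to the synthetic palette; real imagery
  should use the pluggable external segmenter.
- The biomass regressor is trained against simulated curves, so its
  "truth" inherits their treatment-level granularity.
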