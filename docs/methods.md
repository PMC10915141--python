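# Methods

## What this package models

Human vision is never uniformly sharp: objects off the plane of fixation are
defocused, and resolution falls steeply from the fovea to the periphery.
`blurvision` implements the computational consequences of taking that fact
seriously when training convolutional image classifiers. It contains (1) an
optically derived law for sampling Gaussian blur during training, (2) a
battery of probes that measure what blur-augmented training does to a
network — spatial-frequency tuning, representational geometry, encoding-model
predictivity, shape-vs-texture bias, corruption and adversarial robustness,
pixel-wise relevance — and (3) a synthetic data module that generates every
input the battery needs with known ground truth, so the whole analysis runs
on a single CPU in minutes.

## The blur-augmentation laws

**Optics.** An object at relative defocus D (diopters) viewed through a
pupil of diameter p (m) spreads a point over a blur circle of angular
diameter ≈ p·D radians (small-angle thin-lens geometry; no eye-size
corrections). For a photograph of horizontal field-of-view θ spanning W
pixels, that angle converts to pixels at W/θ px/deg. A Gaussian kernel is
matched to the blur circle by FWHM: σ = FWHM / (2√(2 ln 2)). Defaults: pupil
5.8 mm, 54° field of view, 224 px — one diopter of defocus then equals
≈ 1.38 px of blur circle, σ ≈ 0.59 px.

**Weak-blur law.** Mapping task-weighted defocus observations from everyday
viewing through that chain, binning σ to the integer grid 0–5 and smoothing
the nonzero-σ mass with a fitted decaying exponential (least squares on
log-frequency; the σ=0 mass is kept as the empirical point mass) yields the
canonical weak regime: P(σ=0..5) = (69.4, 21.3, 6.5, 2.0, 0.6, 0.2)%.
`weak_blur_reference()` returns these published values directly;
`derive_weak_blur_distribution()` exposes the derivation for user-supplied
defocus samples and is validated by an exact exponential round-trip, not by
reproducing the reference numbers (the original eye-tracking data are not
part of this package).

**Strong-blur law.** σ ∈ {0, 1, 2, 4, 8} px with equal probability,
emulating the continuum of resolutions present across the visual field. At
σ = 8 on a 224-px image the Gaussian MTF, exp(−2π²σ²(k/W)²), falls below
50% amplitude for every frequency above ~5.2 cycles/image, so only very
coarse structure survives the largest kernel.

**Peripheral blur.** σ(e) ramps linearly from `center_sigma` at the image
center to `max_sigma` at eccentricity `saturation_eccentricity` (Euclidean
distance, in px) and saturates; defaults 0 → 8 px saturating at 112 px.
Implementation blends a stack of uniformly blurred copies quantized every
0.5 px of σ with per-pixel linear interpolation — accurate to the blend
tolerance tested (~1e-3 at the saturated periphery) without per-pixel
kernels.

**Numerical choices.** Kernels are truncated at radius ⌈4σ⌉ and normalized
to unit sum; borders are reflective (edge-inclusive). Blur is re-sampled
independently for every presentation of every image, every epoch. Blur
levels are applied in pixel units as stated at any image size; on 64-px toy
images the σ=8 kernel therefore degrades shape as well as texture, which
impairs but does not abolish classification of those presentations (and is
exactly what pushes learning toward coarse structure).

## The synthetic corpus

A class is a silhouette template (regular polygons, stars, smoothed blobs
with class-fixed radial harmonics) filled with a procedural texture
(oriented gratings, checkerboards, band-passed noise, random dots) on a
mid-gray background; ordinary samples pair silhouette k with texture k,
cue-conflict hybrids pair silhouette a with texture b ≠ a, every ordered
pair equally often. Three generator choices are deliberate and matter for
what the corpus can show:

- Texture statistics are equalized inside the silhouette (fixed mean and
  contrast), so texture identity lives only in high-spatial-frequency
  structure — the cue blur removes. The whole fill then receives a
  per-sample random mean offset (±0.12–0.28) from the background: the
  offset is uninformative about either class, but it keeps the silhouette
  visible as a luminance edge after blurring, as real objects remain
  visible against their backgrounds. Without it, heavy blur would erase the
  image entirely and blurred presentations would carry no training signal.
- Textures are fine (periods ~3 px, noise band 0.22–0.46 cycles/px): they
  survive clear viewing, are attenuated hard by σ ≥ 1, and overlap the
  band that additive pixel noise corrupts most.
- Pose jitter is limited (±0.35 rad rotation, small scale/position jitter):
  natural photographs have broadly canonical poses, and full rotation
  invariance is not learnable from 20 samples/class.

Silhouette area is controlled analytically (shoelace-normalized radius) to
20–45% of the frame. All randomness flows from one seeded generator per
call; corpora are bit-reproducible.

**What the generator does not emulate:** natural image statistics (1/f
spectra, clutter, occlusion), within-class shape variability beyond pose
jitter, color, and style-transfer textures. Passing directional tests here
shows that the blur-training mechanism operates as described on stimuli
whose shape and texture cues are cleanly separated by spatial frequency; it
does not certify effect sizes on natural images.

## The tiny model and training

A three-block CNN (conv–ReLU–maxpool; 8/16/32 channels; 5×5 kernel in the
first layer for a more frequency-selective front end, 3×3 thereafter)
followed by one more average pooling, flatten, and a linear head. The
flatten head (rather than global average pooling) retains the coarse
spatial layout of the final feature map — a classifier reading silhouettes
needs to know *where* features are, and global pooling removes exactly
that. Layers are all implemented in `blurvision.nn`, a minimal numpy
framework with hand-written backward passes validated against finite
differences; one code path supplies training (Adam, cross-entropy),
input-space gradients (adversarial attacks) and per-layer forward caches
(relevance propagation).

Training defaults: 80 epochs, batch 16, Adam lr 4e-3, seeds fixed. At 64 px
with 4 classes × 20 samples this is ~45 s on one CPU. Shorter runs learn
the task but leave first-layer filters near their random initialization,
which washes out regime differences in layer-1 tuning. A model whose final
accuracy on the clear training images is below chance + 0.15 raises a
training error rather than returning a silently broken handle.

## Probes

**Spatial-frequency tuning.** Whole-field cosine gratings on a full
factorial grid — 25 frequencies (arithmetic ladder up to Nyquist; at 224 px:
4.48…112 cycles/image), 15 orientations (0–168° step 12°), 4 phases
(0/90/180/270°); the grid is stated at 224 px and scaled proportionally so
cycles-per-image coverage is preserved at other sizes. A channel's curve is
its post-ReLU activation averaged over space, orientation and phase at each
frequency; the preferred SF is the argmax (ties flagged, broken toward the
lowest frequency). Bandwidth comes from a Gaussian-plus-offset fit in log2
frequency after subtracting the minimum response (scale-invariant by
construction); reported as FWHM in octaves and as linear FWHM relative to
the peak frequency — both, because "width relative to center" is ambiguous
between the two conventions. Fits with R² < 0.5 are flagged unreliable and
excluded (with counts) from layer means.

**Representational similarity.** Condition-by-feature tables (group means
when a grouping is supplied) → condition×condition Pearson matrix →
similarity of two such matrices as the Pearson correlation of their strict
upper triangles (diagonal excluded; each unordered pair once — using both
triangles would change nothing but double-count). Fisher z = atanh(r) for
averaging/testing, with |r| ≥ 1−1e-12 clipped. Zero-variance condition
vectors raise rather than being silently dropped. Layer-wise similarity
against a target geometry records the peak layer and peak r.

**Encoding models.** (1) PCA+PLS: features standardized on the train split,
PCA to `n_components` (reference 300; capped at min(rank, train−1) with a
note), linear PLS (latent dimension 25 by default), per-neuron test-set
Pearson r, median across neurons, 80/20 split. (2) Regularized Poisson
regression for spike counts with spatially laid-out features: rate =
softplus(w·x + b), mean Poisson NLL minimized by Adam (cap 2000 iterations,
loss-change tolerance 1e-6) plus λ₁‖w‖₁ (λ₁=0.01), λ₂·Σ(squared first
differences over the two spatial axes) (λ₂=0.1), λ₃·Σ_channels‖w_c‖₂
(λ₃=0.001). The smoothness and group-sparsity formulations and the softplus
link are this package's concrete choices for penalties that are usually
named but not formulated; they are validated by planted-teacher recovery,
not by matching any external fit.

**Behavior.** Shape bias = shape-consistent / (shape- + texture-consistent)
decisions on cue-conflict hybrids, argmax restricted to the shared class
set; decisions matching neither cue are counted but excluded from the
denominator; a zero denominator flags the score undefined. Corruptions:
eleven parametric kinds with documented severity schedules (noise schedules
follow the standard corruption benchmark's published parameters; blur
kinds use soft-profile kernels so distortion energy is monotone in
severity; severity 0 is an identity passthrough for testing). PGD: x ←
P(x + α·dir(∇ₓL)), 15 steps, α = 0.001 reference; dir is elementwise sign
for L∞ and the L2-normalized gradient for L2 (sign is not a steepest-ascent
direction in L2 geometry — a documented deviation from writing sign(·) for
both), P projects onto the ε-ball (ε reference 0.001 for L∞, 1 for L2),
iterates clipped to [0,1], random initialization uniform in the ball.
Consistency of two responders: observed = fraction of items both got right
or both wrong; expected = a·b + (1−a)(1−b) for accuracies a, b; error
consistency κ = (observed − expected)/(1 − expected), undefined (flagged)
when expected = 1.

**Relevance propagation.** ε-rule (ε = 1e-9) for strictly feedforward
conv/linear/pool/ReLU stacks: the target unit's output relevance is 1,
redistributed backward proportionally to each input's contribution to each
pre-activation; ReLU passes relevance through, max-pool routes to the
winner, average-pool splits proportionally to activations. At the input,
negative relevance is zeroed and the map linearly rescaled to [0,1].
Conservation is approximate (bias terms and ε absorb mass); the test
tolerance on a zero-bias conv net is 0.05 of the seeded relevance.

## Problem sizes and the directional replications

The regime comparison trains 5 seeds × {clear, strong-blur} on 4-class,
64-px corpora (20 samples/class) and checks three sign-majority orderings:
strong-blur training (i) lowers the mean preferred spatial frequency in
every conv layer, (ii) raises shape bias, and (iii) raises accuracy under
severity 3–5 Gaussian noise. These are directional claims at toy scale —
magnitudes are not comparable to full-scale experiments. The full battery
runs in roughly 12 minutes on one CPU.

## Known limitations

- The weak-blur derivation's exponential family and fitting domain are a
  documented approximation; the published reference distribution is the
  canonical regime.
- The Poisson encoding model's penalties are this package's formulations of
  named-but-unformulated regularizers.
- The LRP variant is the plain ε-rule; other rules (αβ, z⁺) are not
  implemented.
- Residual/recurrent/attention topologies are out of scope everywhere a
  strictly feedforward stack is assumed (LRP, layer enumeration).
- The corruption schedules are package-defined except where noted; they are
  monotone and documented but not numerically identical to any external
  benchmark.
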