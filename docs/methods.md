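# Methods

## Model

The network maps a low-resolution (LR) MRI slice, already resampled to the
high-resolution (HR) grid by linear interpolation, to an HR estimate. It is
grid-preserving: no in-network upsampler exists, matching an image-domain
degradation pipeline in which LR and HR live on the same grid. Two global
residuals — features (embedding output added to the last stage output) and
image (input added to the reconstruction) — anchor the network at the
identity map.

### Scan orderings

Tokens are pixels (patch size 1) after a 3×3 convolutional embedding;
preserving resolution matters for super-resolution, and the depthwise
convolution inside each block supplies the local patch mixing. A scan order
is a bijection of the H×W grid with an explicit inverse. The eight-path set
is the product {horizontal, vertical, anti-diagonal, main-diagonal} ×
{forward, reverse}; this factorization covers the three scan families
bidirectionally. With four paths, only forward traversals are kept so every
family stays represented. Conventions fixed for testability: anti-diagonals
d = r + c are enumerated in increasing d with increasing row inside each
diagonal; the main-diagonal order is the anti-diagonal order of the
column-mirrored grid, mirrored back; the zigzag order is JPEG-style
(odd diagonals top→bottom, even bottom→top). Cell indexing is row-major,
0-based.

### Selective recurrence

Per head, `h_t = exp(Δ_t A) h_{t−1} + Φ(Δ_t, A) B_t u_t` and
`y_t = C_t h_t + D u_t`, with `A = diag(−exp(a))` so every decay factor
`exp(Δ A)` lies strictly in (0, 1) for Δ > 0 regardless of the learned `a`.
`Φ(Δ, A) = (exp(ΔA) − I) A^{−1}` is computed elementwise; for |ΔA| < 10⁻⁶ a
two-term Taylor expansion `Δ(1 + ΔA/2)` replaces the direct formula to avoid
catastrophic cancellation (the same threshold switches the corresponding
term in the backward pass). Δ is predicted per token and head by a
two-layer channel MLP under a softplus, shared across the state dimensions
of that head. `B_t`/`C_t` are input-dependent (selective) linear projections
of the token by default; a static variant is switchable in the
configuration because the recurrence is also well defined with constant
B/C. Hidden state starts at zero for every sequence; nothing is carried
across slices. Each of the m = 8 heads consumes the full channel vector and
is bound to one scan order; head outputs are concatenated (8·C channels),
layer-normalized over that axis, gated multiplicatively by
`SiLU(W_g v)` of the scan input (gating is on by default, switchable), and
projected back to C channels. State size defaults to N = 8 per head.

Three routes to the recurrence coexist: a literal per-timestep loop kept as
an oracle, a vectorized single-head scan, and a batched multi-head engine
with hand-derived analytic gradients whose sequential core is fused into
single-pass kernels (numba-jitted, with a pure-NumPy fallback that the test
suite checks against the jitted path). The vectorized scan is required to
match the loop oracle to 10⁻¹⁰ in double precision.

### Width under the parameter budget

Depth ([4, 6, 6, 7] block repeats), α = 2, eight diagonal scan paths and
the loss weights are fixed design inputs; the channel width is the derived
quantity: 38 is the largest width keeping the total trainable parameter
count (852,505) under 0.9 M. The test suite asserts both the budget and
that one step wider would break it.

### Initialization

Residual-branch output projections (scan-module projection, Channel-MLP
projection) and the reconstruction head are zero-initialized, so a fresh
model computes the identity on images; all other layers use
He-style Gaussian init. `a` is initialized to log(1..N) per head and the
pre-softplus step-size bias to softplus⁻¹(0.05). Starting at the identity
is what makes short desk-scale training runs meaningful: the model begins
exactly at the interpolation baseline and optimization can only move it
relative to that anchor.

## Training objective

`L = λ·mean|x̂ − x| + ℓ_p`, λ = 4, mean over pixels and batch. The
perceptual term ℓ_p is pluggable. The default backend is a gradient-domain
proxy: the mean squared Prewitt-gradient difference averaged over two
scales (native and 2× average-pooled). It is zero for identical images,
symmetric, differentiable, and penalizes the loss of edge energy — the
property the perceptual term exists for — but it is *not* a learned
distance and does not emulate any pretrained network; real LPIPS backends
can be registered through the same interface (grayscale inputs would be
channel-replicated). Optimization is Adam (β = 0.9/0.999) at 2×10⁻⁴, batch
8, 30 epochs, no schedule, no augmentation; slices are shuffled by a seeded
RNG and the whole run is a pure function of the seed.

## Preprocessing

Volumes are normalized by `clip((v − P1)/(P99 − P1), 0, 1)`; percentiles
use linear interpolation between order statistics and are taken over all
voxels, or over foreground voxels when a mask is supplied (mask generation,
e.g. skull stripping, is external). Degradation is image-domain linear
resampling to the coarse grid and, for the network input, linear resampling
back to the original grid; constants are preserved exactly. Presets:
`brain4x` = isotropic factor 4 (0.8 mm → 3.2 mm); `prostate` = 3× per
in-plane axis and 2× through-plane — the stated in-plane factor 9 is an
area factor, the only reading consistent with a 0.66 mm → ~2 mm spacing
change; `inplane2x` = 2× in-plane only, used for desk-scale training
experiments where stronger factors would leave almost nothing recoverable
on 32×32 phantom slices. Slice selection trims five slices at each end and
drops slices whose exactly-zero-voxel fraction exceeds 95 % (a slice at
exactly 95 % is kept); "background" means exactly zero after
masking/normalization. The slicing axis is the third array axis.

## Metrics

All metrics assume [0, 1] single-channel slices (`data_range` fixed at 1
after normalization, not per-image). SSIM is the Gaussian-window Wang-2004
form (11×11, σ = 1.5, K1 = 0.01, K2 = 0.03, population covariances, border
of half a window cropped); the suite cross-checks it against scikit-image
to 10⁻⁶. GMSD uses Prewitt /3 kernels with replicate boundaries — zero
padding would manufacture spurious boundary gradients and break the
degenerate-case identities (constant images score exactly 0) — and the
population standard deviation of the similarity map, with c = 170/255²
rescaled from the original 8-bit formulation. The perceptual metric
dispatches to the same backend registry as the loss and falls back to the
gradient proxy with a logged warning when a requested backend is absent.

## Reader-study statistics

Kruskal–Wallis H is computed from rank sums with the standard tie
correction and a χ² reference distribution (k − 1 df); Dunn's pairwise z
uses the tie-corrected variance and the large-sample normal approximation,
with Holm step-down adjustment (sort ascending, multiply the k-th by
m − k + 1, enforce the running maximum, cap at 1). For Likert scores, each
instance (dataset × reader × case) contributes a win, loss or tie per
method pair; the preference rate is wins/(wins + losses) with ties
excluded, and significance is an exact two-sided binomial test at p₀ = 0.5
computed by tail doubling over exact binomial coefficients (at p₀ = 0.5
this coincides with the minimum-likelihood definition). Pairs with no
shared instances are flagged and excluded from per-method overall rates.
Descriptives use the sample standard deviation and interpolated quartiles.
The preference matrix puts 0.5 on the diagonal by convention.

## Synthetic data

Phantoms are compositions of overlapping random ellipsoids (Shepp–Logan
tradition): piecewise-smooth regions with sharp boundaries, plus an
optional band-limited texture (Gaussian-filtered noise restricted to the
foreground) and additive Gaussian noise, clipped to [0, 1.2] before
normalization. They exercise exactly what super-resolution must restore —
edges and texture — and nothing else: no coil profiles, bias fields,
k-space sampling or realistic tissue statistics. Passing tests on phantoms
therefore demonstrates that the pipeline optimizes and generalizes on
piecewise-smooth imagery, not clinical performance. Reader tables are
simulated as `score = round(clip(q_method + bias_reader + ε, 1, 5))` with
Gaussian reader bias and noise — the simplest structure with a known
planted preference ordering. Every generator is a pure function of its
spec and seed.

## Desk-scale experiment sizes

The training-gate experiment uses a tiny model (stages [1, 1, 1, 1], width
16), eight 32×32 phantom training pairs drawn one middle slice from each of
eight volumes, four held-out pairs from four further volumes, the
`inplane2x` degradation, batch 2, and 500 Adam steps, repeated for three
seeds with a majority decision; drawing the pairs from distinct volumes is
what makes the learned sharpening generalize rather than memorize. The
overfitting smoke test uses a single 32×32 pair for 200 steps. The FLOP
estimator counts multiply-adds analytically per layer (linear in the pixel
count); at the 288×288 brain matrix size the default model lands in the
tens of GFLOPs, the same order as published efficiency figures, but exact
reproduction of any printed FLOP number is not claimed since counting
conventions and the reference resolution are not fixed.

## Known limitations

- CPU/NumPy training is practical only at desk scale; the full-scale
  training runs behind published clinical results are out of scope.
- The gradient-domain perceptual proxy is a stand-in; conclusions about
  perceptual quality under a learned distance require plugging in a real
  LPIPS backend.
- Phantom realism is deliberately minimal (see above).
- 3D/volumetric variants, multi-contrast inputs and learned scan orders are
  out of scope.
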