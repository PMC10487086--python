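# Methods

`augbench` implements a 3D augmentation suite and a cross-validated 3D CNN
benchmarking protocol for volumetric fMRI derivative maps (e.g. regional
homogeneity), together with a synthetic phantom generator so that every
stage — I/O, augmentation, the classifier, the protocol — is exercisable and
testable without access to an external cohort.

## Data model

Inputs are single-subject 3D scalar derivative volumes in NIfTI-1, nominally
61 × 73 × 61 voxels at 3 mm isotropic in MNI152 space, paired with a CSV
manifest (`subject_id, label, site_id, volume_path`) carrying a binary
diagnosis label (1 = patient, 0 = control). Volumes are stored and processed
in 0-based voxel coordinates with axis order (x, y, z) matching the on-disk
array layout. NaN voxels — background outside the brain mask in some
derivative distributions — are replaced by 0 on read, with a logged warning.
No intensity standardization is applied at load time; an optional per-volume
divide-by-max mode is exposed on the training configuration (default off)
for users whose derivative pipeline performs no intensity normalization.

## Augmentation families

Five families, each drawn fresh per training sample per epoch ("on-the-fly"
augmentation); validation and test volumes are never augmented.

| family      | parameter, units                  | default / studied values |
|-------------|-----------------------------------|--------------------------|
| flip        | probability of mirroring x        | 0.5                      |
| rotation    | per-axis angle bound, degrees     | 7.5, 15, 30, 45          |
| scaling     | per-axis factor bound, fraction   | ±0.10, ±0.20             |
| brightness  | gain g and exponent γ, unitless   | both U(0.8, 1.2)         |
| elastic     | control-point sd σ, voxels        | 2, 4, 6, 8               |

Brightness is the power law `I_new = g · I^γ`; negative inputs are clamped
to 0 first, since derivative maps such as REHO are non-negative and
non-integer powers of negatives are undefined. Elastic deformation draws
i.i.d. Normal(0, σ²) displacements per axis on a square control grid
(default spacing 8 voxels, exposed in the config since the coarse-grid
spacing is otherwise a free choice) and upsamples them to voxel resolution
with an order-3 spline, so the field passes exactly through the control
values at grid locations.

Design choices where the design was genuinely open:

* **Rotation center** is the geometric volume center ((N−1)/2 per axis),
  which avoids translating the brain out of the field of view.
* **Axis composition order** is fixed: rotate about x, then y, then z, then
  scale per axis about the same center.
* **One resampling for rotation + scale**: both are composed into a single
  output-to-input (pull-back) affine, so the pair costs one interpolation.
  The full pipeline is sequential — flip → affine → elastic warp →
  brightness — rather than one fused warp, keeping the families independent
  and individually measurable.
* **Image resampling order** defaults to 1 (trilinear) with constant fill 0
  and boundary blending against the fill value (`grid-constant` semantics);
  the order-3 spline is reserved for the displacement-*field* upsampling,
  which is where a smooth interpolant matters. Both orders are configurable.
* **Identity limits are exact**: 0°, unit scale, σ = 0 and g = γ = 1 each
  short-circuit to a bitwise copy, never a resampling through an identity
  matrix. This makes "identity augmentation equals no augmentation" a
  testable exact statement rather than an approximation.
* **Per-axis scale factors** are drawn independently per axis, matching the
  per-axis description of the transform.

Numerical verification: the affine and elastic resampling kernels are tested
against brute-force per-voxel interpolation oracles on ≤ 11³ volumes
(agreement to 1e−6 for orders ≤ 1), and sampled parameters are checked
against their uniform laws over 10,000 draws.

## Synthetic phantom

The generator emulates the *qualitative* structure of REHO derivative maps:
non-negative, spatially smooth scalar fields inside an ellipsoidal brain
mask (semi-axes 45% of each grid dimension), with a localized class effect
inside one or more ellipsoidal regions and optional multiplicative per-site
gains (default U(0.8, 1.2) over 3 sites) emulating multi-scanner brightness
differences.

Two modes:

* **direct** — each subject is a shared smooth base pattern plus smoothed
  Gaussian noise, with the class effect added inside the effect regions.
  `noise_sd` is defined as the sd of the *smoothed* field inside the mask
  (the raw noise is smoothed, then rescaled), so effect magnitudes read
  directly in within-region SD units. Defaults: noise_sd 0.1, smoothness
  2 voxels, effect magnitude 0.15 (a 1.5 SD effect).
* **via_timeseries** — each subject gets a simulated 4D series (default 60
  frames of spatially smoothed, frame-wise unit-variance noise); inside each
  effect region a shared regional time course is mixed in with coupling
  weight = magnitude for patients and magnitude/2 for controls, raising the
  local temporal concordance. The derivative is then computed by a real
  regional-homogeneity pass.

Regional homogeneity is Kendall's coefficient of concordance over each
in-mask voxel's cube neighbourhood (7, 19 or 27 voxels; default 27, the
common choice):

    W = 12 · Σ_t (R_t − R̄)² / (K² (n³ − n))

with R_t the cross-voxel rank sum at time point t and K the number of
in-mask, in-grid neighbours (K shrinks at mask and grid boundaries rather
than padding, which would bias W). Ties take midranks with no tie-correction
term — the simulated data are continuous, so ties have measure zero. The
implementation is a vectorized shift-and-sum; the test suite holds it to
1e−10 agreement with a naive ranked-loop implementation, and to the
analytic anchors W = 1 (identical series), W = 0 (two fully discordant
series) and E[W] ≈ 1/K under independence.

What passing phantom tests does **not** show: the phantom has no
hemodynamics, head motion, registration error, age/sex structure, or the
value distributions of any particular preprocessing pipeline. Results on it
validate the *machinery* (augmentation correctness, training protocol,
paired benchmarking), not clinical classification performance.

## Classifier

A small 3D CNN: three 3×3×3 convolutions with ReLU (8, 8, 16 filters),
2×2×2 max-pooling after the first and second convolutions, valid padding, a
16-unit ReLU dense layer and a single sigmoid output. On the standard
61 × 73 × 61 grid this gives exactly 439,129 trainable parameters
(224 + 1,736 + 3,472 + 433,680 + 17), i.e. approximately 450 k. The
pool/padding schedule is pinned by that count: pooling after all three
convolutions gives ~50 k parameters and same-padding with three pools
~118 k, both far from the nominal figure. The dense layer's ReLU is a
conventional choice for a penultimate layer.

The network is implemented directly in NumPy: convolutions run as an im2col
GEMM forward pass, and the input gradient accumulates one small GEMM per
kernel offset (avoiding the k³-fold expansion of the upstream gradient,
which is the memory bottleneck at these sizes). Training uses binary
cross-entropy on the logits and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−7).
Backpropagation is verified against central-difference numerical gradients
in float64 (relative error < 1e−6) for both padding modes. Weight
initialization is He-scaled and deterministic given the seed; inference is
batch-composition invariant. Classification thresholds the sigmoid output
at 0.5, boundary inclusive.

## Training and benchmarking protocol

* **Splits**: stratified random 70/15/15 train/validation/test. Subset
  sizes use largest-remainder rounding of n·fraction (1112 subjects give
  778/167/167) and the per-class allocation is adjusted to meet both the
  class totals and the global subset sizes exactly.
* **Cross-validation**: the protocol pairs a fixed 70/15/15 split ratio
  with k-fold averaging, which a rotating-fold scheme cannot realize; it is
  therefore implemented as k repeated stratified random splits (Monte-Carlo
  CV) with per-fold seeds `seed + fold`. Fold-to-fold variance under this
  scheme includes split variability, which is what the reported sd over
  folds is meant to capture.
* **Stopping regimes**: early stopping monitors validation accuracy
  (improvement = strictly greater than the running best), halts `patience`
  (default 50) epochs after the last improvement, restores the
  best-validation weights, and is capped at `max_epochs` (default 500) to
  bound runtime; or a fixed run of 150 epochs keeping the final weights.
  Reference optimization settings: Adam, learning rate 1e−5, batch size 16.
* **Paired benchmarking**: every augmentation strategy trains on identical
  per-fold splits and identical weight initializations, so strategy deltas
  are paired differences. The summary reports mean, sd over folds (n−1
  denominator) and delta vs the mandatory `none` baseline in percentage
  units to one decimal. Deltas are antisymmetric by construction.

## Desk-scale study conditions

The self-contained benchmark used by the test suite and the acceptance
script runs on a separable phantom: 24³ volumes, 100 + 100 subjects, one
site with unit gain, a centred effect region (semi-axes 22% of each
dimension) at 1.5 within-region SD, 3 folds, 30 fixed epochs, batch 16, and
strategies none / identity-rotation-0 / flip / rotation 15°, plus a
permuted-label chance control. At this scale the classifier has ~7.5 k
parameters and sees 270 optimizer steps, for which the reference learning
rate of 1e−5 (tied to the full-size model and hundreds of epochs) cannot
converge; the desk-scale runs therefore use Adam's conventional 1e−3. The
expected outcomes are structural: baseline test accuracy well above 0.9 on
the separable phantom, an exactly-zero delta for identity augmentation under
shared seeds, and chance-level accuracy (0.5 within binomial noise over 90
test decisions) with permuted labels.

## Degenerate inputs and tie-breaks

* Splits require ≥ 3 subjects per class; smaller classes raise a
  stratification error.
* Largest-remainder ties are broken by stable order (train, validation,
  test).
* `apply_affine` rejects singular matrices; out-of-grid lookups receive the
  configured fill value.
* `compute_reho` requires ≥ 3 time points and a non-empty mask; W is clipped
  to [0, 1] against floating-point overshoot at the boundaries.
* Max-pooling crops odd trailing voxels (floor division), matching the
  shape arithmetic used by the parameter count.

## Known limitations

* No GAN-based or test-time augmentation; no 2D slice augmentation.
* No multi-channel (multi-derivative) input and no multi-class severity
  grading.
* The CNN is CPU-only NumPy; it is sized for desk-scale grids. Full-size
  61 × 73 × 61 training works but is slow without a GPU framework.
* Site membership is not balanced across splits (only stratified by label).
* Accuracy is the only reported metric, appropriate for balanced cohorts;
  no significance testing of strategy deltas is performed.
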