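# Methods

## Problem setting

Photoacoustic tomography reconstructs the optical absorption of tissue
from ultrasound transients recorded by an array of N detector elements
(M time samples each). Practical systems rarely satisfy the exact
reconstruction conditions — too few elements, or too little angular
coverage — and analytic reconstructions (delay-and-sum, universal
back-projection) then carry streak artifacts and amplified noise.

The observation this package builds on: artifact pixels are sensitive to
the detection configuration, while true absorbers reconstruct consistently
no matter which elements are used. Reconstructing many images from random
element subsets and measuring their pixelwise agreement therefore
separates structure from artifact, and that agreement map can regularize
the full-array reconstruction — without ever solving the acoustic forward
model inside the iteration.

## The coherence prior

Given k reconstructions R_1..R_k from random subsets of s < N elements,
the coherence map is

    D = (R_1 + ... + R_k)^2 / (k (R_1^2 + ... + R_k^2)),

elementwise. By Cauchy-Schwarz, D ∈ [0, 1], with D = 1 exactly where all
subset values agree and are nonzero (that equality is assigned directly in
code so floating-point rounding in the ratio cannot blur the bound);
pixels where every subset value is zero carry no signal and get D = 0.

D is sharpened by a global weighting built from its own distribution:
with vmin = min D, vmax = max D, μ = (vmax + vmin)/2, σ = (vmax − vmin)/6,

    P = D · ∫_{vmin}^{D} Φ(v | μ, σ) dv,

where Φ is the normal CDF; the integral is evaluated with the closed-form
antiderivative σ·[z·Φ₀₁(z) + φ₀₁(z)], z = (v − μ)/σ. The weighting pushes
the map toward the extremes: strongly coherent regions are emphasized,
weak ones suppressed but not discarded. Finally Pnorm = (P − min P) /
(max P − min P) ∈ [0, 1]. A constant P field (including the constant-D
case, where σ = 0) yields the non-informative prior Pnorm ≡ 1 with a
logged warning, so a non-discriminating prior suppresses nothing. The
step-function truncation of the integral is taken upper-limit inclusive
(u(0) = 1), a measure-zero convention fixed for determinism.

Subsets are drawn uniformly without replacement within a subset and
independently across subsets (overlap allowed; a disjoint partitioning
mode exists). A practical default for s is about N/10; defaults here are
k = 50, configurable. One consequence of overlapping subsets worth
knowing: two subsets share ~s/N of their elements on average, so even
pure noise has baseline coherence near s/N everywhere. The prior's
discriminating power is therefore in its spatial localization (coherence
peaks on true structure), not in the global mean of the map.

## Regularized iteration

The full-array reconstruction R_N is mapped to [0, 1] by taking absolute
values and min-max scaling (magnitudes are what the coherence prior
describes; a signed mode is available), then refined by minimizing

    L(R_op) = λ_con ‖R_N − R_op‖²_F + λ_reg ‖(1 − Pnorm) ⊙ R_op‖²_F

from the start point R_op = R_N. The data-consistency term anchors the
iterate to the measurement-derived image; the regularization term shrinks
pixels the prior marks as incoherent. The objective is convex and
pixel-separable with unique minimizer

    R_op* = λ_con R_N / (λ_con + λ_reg (1 − Pnorm)²),

which the package exposes (`closed_form_solution`) and uses as a test
oracle. Starting at R_N makes Pnorm ≡ 1 an exact fixed point, and λ_reg=0
returns R_N unchanged.

Two gradient conventions for the regularizer are shipped: the exact
derivative 2(1 − Pnorm)² ⊙ R_op (default) and an "as-printed" single-factor
variant 2(1 − Pnorm) ⊙ R_op. Both are descent directions for the convex
objective; they coincide at Pnorm ∈ {0, 1} and converge to slightly
different fixed points (the single-factor variant effectively regularizes
with weight (1 − Pnorm) instead of its square). The data-consistency
gradient is implemented with the descent sign, 2(R_op − R_N).

### Optimizer

Minimization uses Adam with bias correction. β2 = 0.999 and ε = 1e−8 are
the usual values; β1 defaults to 0.99 rather than the more common 0.9.
The reason: this objective is a deterministic quadratic with no gradient
noise, and at some curvature × learning-rate combinations Adam with
β1 = 0.9 settles into small period-2 limit cycles around the minimizer
(deviations of order 1e−3 that do not shrink with more iterations, which
an independent scalar-Adam simulation reproduces). The heavier first-moment
average damps the sign-alternating gradients of those cycles: at
lr = 0.01 a 5000-iteration run reaches the closed-form minimizer to
~2e−11 on a 32×32 field, and short runs (50 iterations, lr = 0.001) keep
the loss monotone after the first few steps. Reference weight/iteration
presets are bundled: λ_con/λ_reg = 0.1/0.9 with 50 iterations
(hemispherical 3D study), 0.2/0.8 with 150 iterations (2D ring study),
and 0.1/0.9 with 50 iterations (synthetic matrix-array study), all at
lr = 0.001.

Note the preset iteration budgets stop well short of the quadratic
minimizer (Adam steps are bounded by roughly lr per iteration, so 150
iterations at lr = 0.001 move a pixel at most ~0.15 on the [0, 1]
scale); the iteration is a partial shrinkage toward R_op*, which tempers
how aggressively low-coherence signal is suppressed.

## Synthetic data path

The package is exercised end to end without external data.

**Geometries.** Full ring arrays (element i at angle 2πi/N) and
hemispherical bowls. For the bowl the elements are laid out with a
deterministic golden-angle (Fibonacci) scheme over the band between the
equator and the illumination aperture — a pole cap of the configured
height kept element-free; the reference configurations are a 256-element
ring of radius 5 cm and a 1024-element hemisphere of radius 4 cm with a
1 cm aperture.

**Phantoms.** Uniform disks/spheres (amplitudes add where they overlap)
and a seeded random-walk vessel generator: tubular branches with slowly
drifting directions, rasterized and blurred to a smooth cross-section,
values in [0, 1]. Both are pure functions of (grid, parameters, seed).

**Forward model.** Channel data are simulated by a discretized
circular-mean (2D) / spherical-mean (3D) projection: voxel values are
accumulated into half-open distance shells of width c/fs around each
detector (nearest-bin assignment, normalized by the analytic shell
measure), and the shell profile is differentiated in time by central
differences. This linear operator reproduces geometric times of flight
and a wideband bipolar pulse — the ingredients that produce sparse-view
streaks — and is what the desk-scale studies and tests run on. It does
not model full-wave propagation, acoustic heterogeneity, attenuation,
element directivity, or finite element size, so amplitudes are not
quantitatively those of a physical system, and test results on it
demonstrate the behavior of the prior and optimizer, not system-level
image quality on real hardware.

**Reconstruction.** DAS back-projects each element's trace at the
geometric delay with linear temporal interpolation (out-of-window delays
contribute zero); UBP applies the filter b(t) = 2p(t) − 2t·dp/dt (absolute
time, central differences, one-sided at the trace ends) before the same
back-projection. Weights are uniform with a 1/|elements| normalization and
no solid-angle factor: element-exchangeable weighting puts subset images
and the full image on one scale and gives the exact identity "full-array
image = mean over a disjoint partition of elements", which is what makes
the coherence ratio interpretable. Negative values are retained in
reconstructions; magnitudes are taken only for presentation, metrics, and
the optimizer's normalization step.

## Metrics

PSNR with peak 1 (images are compared as magnitudes, each independently
min-max normalized — the normalization is per image, not joint), SSIM
with the standard constants (K1 = 0.01, K2 = 0.03, uniform 7-wide window,
data range 1), CNR between two disjoint index boxes in the
amplitude-ratio convention 20·log10(|μ_s − μ_n|/σ_n) (a power-ratio
factor-10 variant is available), and Pearson correlation of intensity
profiles along explicit voxel paths.

## Numerical choices and degenerate inputs

- Coherence: 0/0 pixels (all subset values zero) → D = 0; exact-equality
  pixels → D = 1 assigned directly; the ratio is clipped to [0, 1] against
  rounding overshoot.
- Prior integral: closed form validated against adaptive quadrature to
  better than 1e−8; d outside [vmin, vmax] is a domain error.
- Constant-P prior → Pnorm ≡ 1 (warning logged).
- Normalization of a constant image is an error (there is no scale).
- Shell radii at the first samples are floored at half a bin width so the
  2D/3D shell measures never divide by zero.
- Forward simulation raises a window error naming the required sample
  count M when the acquisition window does not cover the farthest
  contributing voxel.
- Divergence (non-finite iterate) raises an error naming the iteration.

## Scaled-down study sizes

The bundled ring demonstration uses a 64-element ring of radius 2 cm, a
128×128 grid at 0.2 mm, a three-disk phantom, and a prior from k = 30
subsets of s = 8 elements with a fixed plan seed; it completes in seconds
on one CPU, and the same configuration drives the reproducibility checks
(fixed seeds give byte-identical prior, output image, and metric report).
Test fixtures are smaller still (32-element ring, 64×64 or 65×65 grids).

## Known limitations

- On the disk demo, PSNR gains from the refinement are marginal (within
  ±0.2 dB of plain UBP depending on the subset plan), while SSIM
  (≈0.05 → ≈0.55) and the background (outside-support) energy fraction
  (≈0.44 → ≈0.18) improve decisively for every plan tried. The reason is
  that the analytic forward model plus unweighted UBP is edge-enhancing:
  disk interiors reconstruct at ~0.4 of their true amplitude, that
  interior deficit dominates the MSE, and a shrinkage-only refinement
  cannot restore missing amplitude. Thin structures (vessels), where
  reconstruction is faithful and background suppression dominates, are
  the favorable regime.
- The prior degrades when artifacts dominate the subset reconstructions
  (extremely sparse or limited-angle views): coherent streaks shared by
  most subsets are indistinguishable from structure.
- The multiplicative DAS variant used by some synthetic-aperture systems
  is not implemented; plain DAS is.
- 2D uses the 3D-style UBP filter; no exact 2D filtration (half-derivative)
  is attempted.
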