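# Methods

This note records the model as implemented, the numerical choices that are
not forced by the formulation, what the synthetic phantoms do and do not
emulate, and the package's known limitations.

## Pipeline

1. **Enhancement.** Each pixel is replaced by a normalized weighted sum of
   its 8 neighbors (3×3 window, center excluded). The weight of neighbor
   x_j is `exp(-C_j / l) * exp(-(x_j - x_i)^2 / sigma_i)`, with
   C_j = var/mean² over the window around x_j (an epsilon of 1e-8 in the
   denominator guards zero-mean background windows) and sigma_i the
   population standard deviation of the eight squared differences
   (x_j − x_i)². On a locally uniform patch sigma_i = 0 and all kernel
   distances are set to 1. Normalizing the weight vector to unit sum makes
   the operator a convex combination: constant regions are reproduced
   exactly and no new extreme intensities can appear. Borders use
   edge-including reflection, the same rule `scipy.ndimage` applies.
   The bandwidth l defaults to 1.0 on the dimensionless C values.
2. **Fuzzy clustering.** Standard FCM (fuzzifier m = 2, tolerance 1e-5,
   at most 300 sweeps) on the enhanced intensities. The objective is
   non-convex and one-dimensional quantile initialization can collapse two
   centers into a heavy dark mode, so the alternation restarts from even
   quantiles, extreme quantiles and seeded k-means++ draws (5 inits) and
   keeps the lowest objective. Classes are then relabeled dark → class 1
   (CSF), brightest → class 2 (WM), remaining → class 3 (GM); this is
   purely a labeling convention and scoring realigns labels anyway.
3. **Level-set evolution.** phi1/phi2 start as ±c0 steps (c0 = 2) from the
   hard FCM assignment (argmax, ties to the lower class index). Each outer
   iteration takes one explicit Euler step (dt = 0.1) of the gradient flow,
   then solves the normal equations A w = v for the bias coefficients,
   renormalizes the bias to unit mean (rescaling the centers to absorb the
   b·c scale ambiguity), and updates the centers in closed form. The loop
   stops when successive center vectors differ by at most 0.001 in
   max-norm, or after max_iters (500).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| nu | 0.001·255² | contour-length weight, in squared-intensity units on the 0–255 scale |
| mu | 1.0 | distance-regularizer weight |
| dt | 0.1 | explicit Euler step |
| heaviside_eps | 1.0 | transition width of the arctan Heaviside (pixels of phi) |
| kernel_sigma | 4.0 | std of the Gaussian clustering window K, radius 2·sigma |
| legendre_order | 3 | total degree of the bias basis (10 basis images) |
| window_radius | 1 | enhancement neighborhood (3×3) |
| phi_max | 30 | saturation bound on \|phi\| |
| conv_tol | 0.001 | stopping threshold on center motion |

Intensities are rescaled to [0, 255] on load because nu is expressed in
255² units; the enhancement is range-preserving, so the scale survives to
the data term.

## Numerical choices

* **Smoothed step functions.** H(phi) = ½[1 + (2/π)·arctan(phi/eps)] and
  its derivative delta(phi) = eps/(π(eps² + phi²)). The (2/π)
  normalization is required for H to be a membership in [0, 1].
* **Weights in the estimation steps.** The per-pixel lambda weights
  multiply the data force that drives phi. The bias solve and the center
  update use uniform weights. The three updates then descend a single
  functional, which is what makes the alternation converge; lambda-weighted
  estimation degenerates as memberships approach one-hot (lambda → 0 on
  each class's own pixels), leaving the bias field constrained only by
  Heaviside-tail leakage. Confidence weighting belongs to the evolution —
  its role is to slow the contour where tissue is already resolved — not
  to the least-squares fits.
* **phi saturation.** |phi| is clamped to phi_max = 30 after every step.
  H is flat there (the transition has width ~eps = 1), so the clamp does
  not move any boundary; without it the arctan tails sharpen indefinitely
  and the center estimates drift at ~0.01 per iteration for thousands of
  iterations, so the stopping rule never fires.
* **Bias basis.** Tensor-product Legendre polynomials of total degree ≤ 3
  on [-1, 1]², sampled on the pixel grid and QR-orthonormalized under the
  discrete inner product (sampling alone is only approximately
  orthogonal). Smoothness of b is structural — any coefficient vector
  yields a polynomial of bounded degree. A w = v is solved directly
  (A is symmetric positive semi-definite); an ill-conditioned solve falls
  back to a small ridge.
* **Kernel and borders.** K is a truncated Gaussian normalized to unit
  sum. All convolutions and finite differences use replicate borders, so
  K∗1 ≡ 1 and the first data-term component needs no kernel factor.
  Replicate-border convolution means the minimizer of the data term is the
  basis projection of K∗b_true rather than b_true itself: recovery of an
  in-span bias is exact with a single-tap kernel and accurate to ~1–2 %
  pointwise (correlation > 0.999) with the default sigma = 4.
* **Curvature.** div(∇phi/|∇phi|) by central differences with
  |∇phi| regularized as sqrt(·² + 1e-10).
* **Degenerate inputs.** An (almost) empty class keeps its previous center;
  FCM pixels exactly on a center get one-hot memberships; fewer than three
  nonempty classes at initialization is an error — the two-level-set
  construction encodes exactly three regions.
* **One-shot bias estimation.** `bias_field.estimate_bias` skips the
  evolution: FCM hard labels give crisp memberships, and the bias solve is
  alternated with the center update to self-consistency (a one-shot solve
  would fold center misestimates into the field). Enhancement is off by
  default here because the fit assumes image = b·c + noise, which the
  neighborhood filter distorts at boundaries.

## The phantoms

`make_phantom` emulates the corruption axes of simulated-brain MRI
repositories: a nested-ellipse three-tissue head (CSF/GM/WM at 45/105/190)
with a wiggly WM/GM interface, multiplied by a seeded random polynomial
bias of unit mean ("40 % inhomogeneity" = 0.4 peak-to-trough), plus
Gaussian noise with sigma a percentage of the brightest tissue mean
("5 % noise" = sigma 9.5); Rician noise is available behind a flag.
`make_weak_boundary_phantom` additionally collapses the WM intensity to
GM + 15 gray levels inside a horizontal band — below twice the noise
sigma at defaults — to emulate the low-contrast interdigitated WM/GM
interface of real slices.

What the phantoms do **not** emulate: partial-volume voxels (every pixel
is pure tissue), non-polynomial coil profiles, anatomical texture within a
tissue, and skull/background. Passing the phantom suite therefore shows
that the energy, its minimization and the bias model behave as designed —
not that real-scanner accuracy will match the phantom numbers, which are
near-perfect precisely because the tissue model is exactly satisfied.
Default problem size is 128×128, large enough for ~17-pixel-radius kernel
structure while keeping a full run at a few seconds.

## Known limitations

* The band of the weak-boundary phantom (WM at GM + 15) is intensity-
  ambiguous for any three-class intensity model, this one included: the
  accuracy margin over plain thresholding comes from cleaning noise- and
  bias-induced errors elsewhere, not from recovering the band.
* The bias field reported by the full iterative pipeline is contaminated
  at the percent level by soft-membership mixing (arctan tails) and by
  drifted center estimates; use `estimate_bias` when the field itself is
  the quantity of interest.
* The two-level-set construction is fixed at three classes; four-phase
  extensions would need a third function or a different encoding.
* 2-D slices only; NIfTI volumes are handled by slice extraction.
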