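# wlsm — weighted level-set segmentation of brain MRI slices

`wlsm` segments 2-D brain MRI slices into white matter (WM), gray matter
(GM) and cerebrospinal fluid (CSF) under the two corruptions that make this
hard in practice: additive noise and the smooth multiplicative intensity
inhomogeneity ("bias field") of MR coils. It is aimed at researchers who
need a classical, fully inspectable alternative to learned segmenters —
no training data, every term of the energy visible.

## The model

A weighted level-set model: two level-set functions (φ₁, φ₂) encode three
tissue regions through products of a smoothed Heaviside H,

    M₁ = 1 − H(φ₁),  M₂ = H(φ₁)H(φ₂),  M₃ = H(φ₁)(1 − H(φ₂)),

and evolve by gradient descent on the energy

    F(Φ, w, c) = ∫ Σₖ λₖ(x) eₖ(x) Mₖ(Φ) dx + ν L(Φ) + µ P(Φ),

where

* **eₖ(x) = ∫ K(y−x) |Ĩ(x) − b(y)cₖ|² dy** is a local intensity-clustering
  data term. `b = wᵀG` is the bias field on an orthonormal Legendre
  polynomial basis G (total degree ≤ 3 by default), `cₖ` are tissue
  centers, and K is a normalized Gaussian window, so each tissue is modeled
  as piecewise constant *after* division by a smooth field.
* **Ĩ** is the input after a weighted-neighborhood enhancement: each pixel
  becomes a convex combination of its 8 neighbors, weighted by
  `exp(−C/l)` (a local-variation coefficient C = var/mean² computed around
  each neighbor) times an adaptive Gaussian kernel distance
  `exp(−(xⱼ−xᵢ)²/σᵢ)` whose bandwidth σᵢ adapts to the local contrast.
  This suppresses noise without moving tissue boundaries.
* **λₖ = 1 − u²ₖ** are per-pixel weights from fuzzy c-means memberships
  uₖ: where clustering is already confident the contour slows down, near
  ambiguous (weak) boundaries it accelerates. They modulate the contour
  evolution and need no manual tuning.
* **L** is the contour length (weight ν = 0.001·255²) and **P** a distance
  regularizer built on a double-well potential p₂ with minima at
  |∇φ| ∈ {0, 1}, which keeps φ close to a signed distance function near
  its zero level with bounded diffusion rate — no re-initialization.

Minimization alternates an explicit Euler step in φ (Δt = 0.1), a linear
solve for the bias coefficients w, and a closed-form center update, until
the centers move less than 0.001 between iterations.

A synthetic phantom generator (`wlsm.phantom`) produces brain-like
three-tissue images with known ground truth, a seeded polynomial bias
field and seeded noise, so the entire pipeline is testable offline.

## Worked example

Generate a 128×128 phantom with 5 % noise and an order-2 bias field,
segment it, and score against the known truth:

```sh
$ wlsm phantom --shape 128x128 --noise 0.05 --bias-order 2 --seed 0 --out ph
wrote phantom to ph
$ wlsm segment ph/image.png --seed 0 --out seg
converged after 79 iterations; centers = 57.51, 189.72, 112.79
wrote seg/labels.png
wrote seg/bias_field.png
wrote seg/corrected.png
wrote seg/energy_trace.csv
wrote seg/run.json
$ wlsm score seg/labels.png ph/truth.png
label permutation : (0, 2, 1)
SA (selected)     : 1.0000  classes (1, 2)
SA (all classes)  : 1.0000
JSC class 0       : 1.0000
JSC class 1       : 1.0000
JSC class 2       : 1.0000
```

The three centers are the estimated tissue intensities (CSF, WM, GM — the
model labels dark/bright/middle, hence the permutation in scoring). `SA`
is segmentation accuracy (correctly labeled pixels over truth pixels;
"selected" restricts to WM+GM), `JSC` the per-tissue Jaccard
intersection-over-union. On this phantom every pixel is recovered.

The same pipeline is available as a library:

```python
import wlsm
img, truth, bias = wlsm.make_phantom(wlsm.PhantomSpec(noise_level=0.05, seed=0))
result = wlsm.segment(img, wlsm.RunConfig(seed=0))
report = wlsm.score(result.labels, truth)
```

Real slices: `wlsm segment slice.png` or
`wlsm segment volume.nii.gz --slice-axis 2 --slice-index 90` (images are
assumed skull-stripped; intensities are rescaled to [0, 255] on load).

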