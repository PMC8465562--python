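"""The weighted level-set energy and its minimization.

Three tissue regions are encoded by two level-set functions (phi1, phi2)
through products of a smoothed Heaviside H:

    M1 = 1 - H(phi1),  M2 = H(phi1) H(phi2),  M3 = H(phi1) (1 - H(phi2)),

which form a partition of unity. The energy

    F(Phi, w, c) = eps(Phi, w, c) + nu * L(Phi) + mu * P(Phi)

combines a kernel-weighted local intensity clustering data term (with the
bias field b = w^T G and per-pixel fuzzy weights lambda_k), the contour
length L, and a distance-regularization term P built on a double-well
potential p2 whose minima at |grad phi| in {0, 1} keep phi close to a
signed distance function near its zero level without re-initialization.

Minimization alternates an explicit-Euler gradient-flow step in phi, a
linear solve for the bias coefficients w, and a closed-form update of the
cluster centers c, until the centers stop moving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import bias_field as bf
from . import enhancement, fuzzy_init
from .io_formats import Image2D, LabelMap, RunConfig

__all__ = [
    "KernelK",
    "EnergyTrace",
    "SegmentationResult",
    "heaviside",
    "dirac",
    "memberships",
    "e_k",
    "double_well",
    "d_p",
    "curvature",
    "phi_step",
    "update_c",
    "total_energy",
    "segment",
]

#: gradient-magnitude regularization in the curvature computation
_GRAD_EPS = 1e-10


@dataclass
class KernelK:
    """Truncated Gaussian clustering kernel, normalized to unit sum."""

    sigma: float = 4.0
    radius: int | None = None

    def __post_init__(self) -> None:
        if self.radius is None:
            self.radius = int(round(2 * self.sigma))
        ax = np.arange(-self.radius, self.radius + 1)
        xx, yy = np.meshgrid(ax, ax)
        win = np.exp(-(xx**2 + yy**2) / (2.0 * self.sigma**2))
        self.window = win / win.sum()

    def conv(self, field_: np.ndarray) -> np.ndarray:
        """K * field with replicate (zero-flux) borders, so K * 1 == 1."""
        return ndimage.convolve(field_, self.window, mode="nearest")


@dataclass
class EnergyTrace:
    """Per-iteration record of F and its components plus the c vector."""

    F: list = field(default_factory=list)
    data: list = field(default_factory=list)
    length: list = field(default_factory=list)
    penalty: list = field(default_factory=list)
    centers: list = field(default_factory=list)

    def append(self, F, data, length, penalty, c) -> None:
        self.F.append(float(F))
        self.data.append(float(data))
        self.length.append(float(length))
        self.penalty.append(float(penalty))
        self.centers.append(np.asarray(c, dtype=float).copy())

    def __len__(self) -> int:
        return len(self.F)

    def rows(self):
        for i in range(len(self.F)):
            yield (self.F[i], self.data[i], self.length[i], self.penalty[i], *self.centers[i])


@dataclass
class SegmentationResult:
    labels: LabelMap
    corrected: Image2D
    bias: Image2D
    enhanced: Image2D
    centers: np.ndarray
    w: np.ndarray
    trace: EnergyTrace
    iterations: int
    converged: bool
    state: fuzzy_init.LevelSetState | None = None
    config: RunConfig | None = None


# ---------------------------------------------------------------------------
# smoothed step functions and region memberships

def heaviside(phi: np.ndarray, eps: float = 1.0) -> np.ndarray:
    """Smoothed Heaviside H(phi) = 1/2 [1 + (2/pi) arctan(phi/eps)]."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(phi, dtype=float) / eps))


def dirac(phi: np.ndarray, eps: float = 1.0) -> np.ndarray:
    """Smoothed Dirac delta, the derivative of :func:`heaviside`."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    phi = np.asarray(phi, dtype=float)
    return (eps / np.pi) / (eps**2 + phi**2)


def memberships(state: fuzzy_init.LevelSetState, eps: float = 1.0) -> np.ndarray:
    """Region membership fields (M1, M2, M3), a partition of unity."""
    h1 = heaviside(state.phi1, eps)
    h2 = heaviside(state.phi2, eps)
    return np.stack([1.0 - h1, h1 * h2, h1 * (1.0 - h2)])


# ---------------------------------------------------------------------------
# data term

def e_k(I_tilde, b: np.ndarray, c_k: float, kernel: KernelK,
        conv_b: np.ndarray | None = None, conv_b2: np.ndarray | None = None) -> np.ndarray:
    """Pointwise clustering residual for one class.

    ``e_k = I^2 - 2 c_k I (K*b) + c_k^2 (K*b^2)``, the kernel-weighted
    squared deviation of the observed intensity from the bias-modulated
    center ``b c_k``. The two kernel convolutions may be passed in
    precomputed since they are shared by all classes. With replicate-border
    convolution ``K*1 == 1``, so the first term needs no kernel factor.
    """
    arr = I_tilde.pixels if isinstance(I_tilde, Image2D) else np.asarray(I_tilde, dtype=float)
    if conv_b is None:
        conv_b = kernel.conv(b)
    if conv_b2 is None:
        conv_b2 = kernel.conv(b * b)
    return arr * arr - 2.0 * c_k * arr * conv_b + c_k**2 * conv_b2


def _e_fields(arr: np.ndarray, b: np.ndarray, centers: np.ndarray, kernel: KernelK) -> np.ndarray:
    conv_b = kernel.conv(b)
    conv_b2 = kernel.conv(b * b)
    return np.stack([e_k(arr, b, ck, kernel, conv_b, conv_b2) for ck in centers])


# ---------------------------------------------------------------------------
# double-well distance regularization

def double_well(s: np.ndarray) -> np.ndarray:
    """Double-well potential p2 with zeros (and minima) at s = 0 and s = 1.

    Piecewise: ``(1 - cos 2 pi s) / (4 pi^2)`` on [0, 1] and
    ``(s + 1) e^(1-s) + s^2/2 - 5/2`` on [1, inf); C^2 across s = 1.
    """
    s = np.asarray(s, dtype=float)
    low = (1.0 - np.cos(2.0 * np.pi * s)) / (4.0 * np.pi**2)
    high = (s + 1.0) * np.exp(1.0 - s) + 0.5 * s**2 - 2.5
    return np.where(s <= 1.0, low, high)


def d_p(s: np.ndarray) -> np.ndarray:
    """Bounded diffusion rate d_p(s) = p2'(s) / s.

    ``sin(2 pi s)/(2 pi s)`` on (0, 1] (value 1 at s = 0 by continuity) and
    ``1 - e^(1-s)`` on [1, inf); |d_p| < 1 on (0, inf) with both limits 1,
    so the regularizing diffusion never blows up and reverses sign only
    inside the well.
    """
    s = np.asarray(s, dtype=float)
    out = np.empty_like(s)
    low = s <= 1.0
    sl = s[low]
    out[low] = np.where(sl > 0, np.sinc(2.0 * sl), 1.0)  # np.sinc(x)=sin(pi x)/(pi x)
    out[~low] = 1.0 - np.exp(1.0 - s[~low])
    return out


# ---------------------------------------------------------------------------
# geometry

def _grad(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gy, gx = np.gradient(phi)
    return gy, gx


def curvature(phi: np.ndarray) -> np.ndarray:
    """div(grad phi / |grad phi|) by central differences.

    The gradient magnitude is regularized by ``sqrt(. ** 2 + 1e-10)``;
    borders use one-sided differences (zero-flux).
    """
    gy, gx = _grad(phi)
    norm = np.sqrt(gx**2 + gy**2 + _GRAD_EPS)
    ny, nx = gy / norm, gx / norm
    return np.gradient(ny, axis=0) + np.gradient(nx, axis=1)


def _dw_diffusion(phi: np.ndarray) -> np.ndarray:
    """div(d_p(|grad phi|) grad phi) — the double-well regularizing flow."""
    gy, gx = _grad(phi)
    mag = np.sqrt(gx**2 + gy**2)
    g = d_p(mag)
    return np.gradient(g * gy, axis=0) + np.gradient(g * gx, axis=1)


# ---------------------------------------------------------------------------
# evolution

def phi_step(
    state: fuzzy_init.LevelSetState,
    lam: np.ndarray,
    e_fields: np.ndarray,
    nu: float,
    mu: float,
    dt: float,
    eps: float = 1.0,
) -> fuzzy_init.LevelSetState:
    """One explicit-Euler step of the gradient flow for both phi's.

    ``dphi_i/dt = -sum_k dM_k/dphi_i lambda_k e_k
    + nu delta(phi_i) div(grad phi_i / |grad phi_i|)
    + mu div(d_p(|grad phi_i|) grad phi_i)``,
    with the membership derivatives taken analytically from the
    three-region products.
    """
    phi1, phi2 = state.phi1, state.phi2
    d1 = dirac(phi1, eps)
    d2 = dirac(phi2, eps)
    h1 = heaviside(phi1, eps)
    h2 = heaviside(phi2, eps)
    le = lam * e_fields  # (3, H, W)

    # dM1/dphi1 = -delta1; dM2/dphi1 = delta1 H2; dM3/dphi1 = delta1 (1 - H2)
    force1 = -(-d1 * le[0] + d1 * h2 * le[1] + d1 * (1.0 - h2) * le[2])
    # dM2/dphi2 = H1 delta2; dM3/dphi2 = -H1 delta2
    force2 = -(h1 * d2 * le[1] - h1 * d2 * le[2])

    new1 = phi1 + dt * (force1 + nu * d1 * curvature(phi1) + mu * _dw_diffusion(phi1))
    new2 = phi2 + dt * (force2 + nu * d2 * curvature(phi2) + mu * _dw_diffusion(phi2))
    if not (np.all(np.isfinite(new1)) and np.all(np.isfinite(new2))):
        raise FloatingPointError(
            "non-finite level-set update; check dt and intensity scaling "
            f"(max|phi1|={np.abs(phi1).max():g}, max|phi2|={np.abs(phi2).max():g})"
        )
    return fuzzy_init.LevelSetState(new1, new2)


def update_c(I_tilde, M: np.ndarray, b: np.ndarray, kernel: KernelK,
             prev: np.ndarray | None = None) -> np.ndarray:
    """Closed-form cluster-center update.

    ``c_k = sum[I M_k (K*b)] / sum[M_k (K*b^2)]``. An (almost) empty class
    keeps its previous center rather than dividing by ~0.
    """
    arr = I_tilde.pixels if isinstance(I_tilde, Image2D) else np.asarray(I_tilde, dtype=float)
    kb = kernel.conv(b)
    kb2 = kernel.conv(b * b)
    num = (arr * M * kb).sum(axis=(1, 2))
    den = (M * kb2).sum(axis=(1, 2))
    tiny = den <= 1e-12 * max(den.max(), 1.0)
    c = np.empty_like(num)
    c[~tiny] = num[~tiny] / den[~tiny]
    if tiny.any():
        if prev is None:
            raise ZeroDivisionError("empty class with no previous center to fall back on")
        c[tiny] = np.asarray(prev, dtype=float)[tiny]
    return c


def total_energy(
    I_tilde,
    state: fuzzy_init.LevelSetState,
    lam: np.ndarray,
    b: np.ndarray,
    centers: np.ndarray,
    kernel: KernelK,
    nu: float,
    mu: float,
    eps: float = 1.0,
) -> tuple[float, float, float, float]:
    """Return (F, data, length, penalty) of the current configuration."""
    arr = I_tilde.pixels if isinstance(I_tilde, Image2D) else np.asarray(I_tilde, dtype=float)
    M = memberships(state, eps)
    ef = _e_fields(arr, b, np.asarray(centers, dtype=float), kernel)
    data = float((lam * ef * M).sum())
    length = 0.0
    penalty = 0.0
    for phi in (state.phi1, state.phi2):
        gy, gx = _grad(heaviside(phi, eps))
        length += float(np.sqrt(gx**2 + gy**2).sum())
        gy, gx = _grad(phi)
        penalty += float(double_well(np.sqrt(gx**2 + gy**2)).sum())
    F = data + nu * length + mu * penalty
    return F, data, length, penalty


# ---------------------------------------------------------------------------
# driver

def _ordered_classes(membership: fuzzy_init.MembershipMatrix) -> fuzzy_init.MembershipMatrix:
    """Fix the three-region labeling convention.

    Class 1 is the darkest tissue (CSF/background), class 2 the brightest
    (white matter) and class 3 the remaining one (gray matter) — purely a
    labeling convention, chosen so phi1 separates dark from bright and phi2
    splits the bright side.
    """
    order = np.argsort(membership.centers)  # ascending
    idx = np.array([order[0], order[2], order[1]])
    return fuzzy_init.MembershipMatrix(
        membership.u[idx], membership.centers[idx],
        fuzzifier=membership.fuzzifier, converged=membership.converged,
    )


def segment(
    image: Image2D | np.ndarray,
    config: RunConfig | None = None,
    callback=None,
) -> SegmentationResult:
    """Full segmentation pipeline for a 3-class brain slice.

    Stages: weighted-neighborhood enhancement; fuzzy c-means for the
    initial centers, level sets and per-pixel lambda weights; then the
    alternating minimization loop (phi step, bias solve, center update)
    until the centers move by at most ``config.conv_tol`` in max-norm or
    ``config.max_iters`` is hit. Deterministic for a fixed seed.

    ``callback(iteration, state, M, b, c)``, if given, is invoked after
    every completed iteration (useful for monitoring and visualization).
    """
    cfg = config or RunConfig()
    if cfg.n_classes != 3:
        raise NotImplementedError("the two-level-set formulation encodes exactly 3 classes")
    img = image if isinstance(image, Image2D) else Image2D(image)
    enhanced = (
        enhancement.enhance(img, cfg.window_radius, cfg.laplace_bandwidth)
        if cfg.enhance
        else Image2D(img.pixels.copy(), source_path=img.source_path, meta=dict(img.meta))
    )
    arr = enhanced.pixels

    membership = fuzzy_init.fcm_cluster(
        enhanced, cfg.n_classes, cfg.fcm_fuzzifier, cfg.fcm_max_iter, cfg.fcm_tol, cfg.seed
    )
    membership = _ordered_classes(membership)
    lam = fuzzy_init.lambda_from_membership(membership)
    state = fuzzy_init.init_levelsets(membership, cfg.c0)

    kernel = KernelK(cfg.kernel_sigma)
    G = bf.legendre_basis(img.height, img.width, cfg.legendre_order)
    # bias starts flat: b = 1 is exactly representable by the constant basis image
    w = np.zeros(G.shape[0])
    w[0] = 1.0 / G[0, 0, 0]
    b = np.tensordot(w, G, axes=1)
    c = membership.centers.copy()

    # The per-pixel lambda weights steer the contour evolution only; the
    # bias and center estimation steps use uniform weights, consistent with
    # the lambda-free center update (confidence weighting degenerates as
    # memberships approach one-hot and would leave b unconstrained).
    lam_flat = np.ones_like(lam)

    trace = EnergyTrace()
    converged = False
    iterations = 0
    c_prev = None
    for it in range(cfg.max_iters):
        ef = _e_fields(arr, b, c, kernel)
        state = phi_step(state, lam, ef, cfg.nu, cfg.mu, cfg.dt, cfg.heaviside_eps)
        # saturate phi: H is flat beyond phi_max, and bounding phi gives the
        # alternating estimation steps a fixed point
        np.clip(state.phi1, -cfg.phi_max, cfg.phi_max, out=state.phi1)
        np.clip(state.phi2, -cfg.phi_max, cfg.phi_max, out=state.phi2)
        M = memberships(state, cfg.heaviside_eps)
        w = bf.solve_w(arr, lam_flat, c, M, kernel.conv, G)
        b = np.tensordot(w, G, axes=1)
        # resolve the b*c scale ambiguity: unit-mean bias, centers rescaled
        scale = float(b.mean())
        if abs(scale) > 1e-12:
            b /= scale
            w /= scale
            c = c * scale
        c_new = update_c(arr, M, b, kernel, prev=c)
        trace.append(*total_energy(arr, state, lam, b, c_new, kernel, cfg.nu, cfg.mu,
                                   cfg.heaviside_eps), c_new)
        # |c(n) - c(n-1)| between successive center updates (max-norm)
        delta = np.inf if c_prev is None else float(np.abs(c_new - c_prev).max())
        c_prev = c_new
        c = c_new
        iterations = it + 1
        if callback is not None:
            callback(it, state, M, b, c)
        if delta <= cfg.conv_tol:
            converged = True
            break

    M = memberships(state, cfg.heaviside_eps)
    labels = LabelMap(np.argmax(M, axis=0).astype(np.int64), cfg.n_classes)
    b_safe = np.where(np.abs(b) > 1e-6, b, 1e-6)
    corrected = Image2D(np.clip(arr / b_safe, 0.0, None))
    bias_img = Image2D(np.clip(b, 0.0, None))
    return SegmentationResult(
        labels=labels,
        corrected=corrected,
        bias=bias_img,
        enhanced=enhanced,
        centers=c,
        w=w,
        trace=trace,
        iterations=iterations,
        converged=converged,
        state=state,
        config=cfg,
    )
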