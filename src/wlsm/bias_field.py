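"""Bias-field model: b(x) = w^T G(x) on an orthonormal Legendre basis.

The multiplicative intensity inhomogeneity of MRI is slowly varying, so it
is modeled as a low-degree polynomial: tensor products of Legendre
polynomials ``P_a(x) P_b(y)`` over all total degrees ``a + b <= order`` on
coordinates normalized to [-1, 1]^2. Smoothness is structural — whatever
the coefficients, the field is a polynomial of bounded degree. The sampled
stack is re-orthonormalized under the discrete pixel inner product so its
Gram matrix is the identity, which keeps the normal equations for ``w``
well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

from .io_formats import Image2D

__all__ = ["BiasFieldModel", "legendre_basis", "solve_w", "eval_bias", "n_basis"]


def n_basis(order: int) -> int:
    """Number of 2-D basis functions of total degree <= order."""
    return (order + 1) * (order + 2) // 2


@dataclass
class BiasFieldModel:
    """Basis stack ``G`` (n_basis, H, W) plus coefficient vector ``w``."""

    G: np.ndarray
    w: np.ndarray
    order: int

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.G.shape[0] != n_basis(self.order):
            raise ValueError("basis stack size inconsistent with order")
        if self.w.shape != (self.G.shape[0],):
            raise ValueError("coefficient vector length must match the basis stack")


def legendre_basis(height: int, width: int, order: int = 3) -> np.ndarray:
    """Orthonormal polynomial basis stack, shape ``(n_basis, H, W)``.

    Pixel centers are mapped affinely onto [-1, 1] per axis; the stack holds
    ``P_a(x) P_b(y)`` for every ``a + b <= order`` (degree-major, then ``a``
    ascending), QR-orthonormalized so the discrete Gram matrix is the
    identity to machine precision. Order 3 gives 10 basis images.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    ys = np.linspace(-1.0, 1.0, height)
    xs = np.linspace(-1.0, 1.0, width)
    px = [npleg.legval(xs, [0] * a + [1]) for a in range(order + 1)]
    py = [npleg.legval(ys, [0] * b + [1]) for b in range(order + 1)]
    imgs = []
    for deg in range(order + 1):
        for a in range(deg + 1):
            b = deg - a
            imgs.append(np.outer(py[b], px[a]))
    stack = np.stack(imgs)  # (n_basis, H, W)
    flat = stack.reshape(stack.shape[0], -1).T  # (P, n_basis)
    q, r = np.linalg.qr(flat)
    q *= np.sign(np.diag(r))  # fix sign so the first basis image is positive
    return np.ascontiguousarray(q.T.reshape(stack.shape))


def solve_w(
    I_tilde,
    lam: np.ndarray,
    centers: np.ndarray,
    M: np.ndarray,
    kernel_conv,
    G: np.ndarray,
    ridge: float = 1e-10,
) -> np.ndarray:
    """Optimal bias coefficients from the weighted normal equations.

    Builds the vector ``v_m = sum_y [K * (I_tilde sum_k lam_k c_k M_k)](y) G_m(y)``
    and matrix ``A_mn = sum_y [K * (sum_k lam_k c_k^2 M_k)](y) G_m(y) G_n(y)``
    and solves ``A w = v``. ``A`` is symmetric positive semi-definite by
    construction; an ill-conditioned solve falls back to a small ridge.

    Parameters
    ----------
    kernel_conv : callable
        ``field -> K * field``, the normalized clustering-kernel smoother.
    """
    arr = I_tilde.pixels if isinstance(I_tilde, Image2D) else np.asarray(I_tilde, dtype=float)
    centers = np.asarray(centers, dtype=float)
    weighted = (lam * centers[:, None, None] * M).sum(axis=0)
    weighted_sq = (lam * centers[:, None, None] ** 2 * M).sum(axis=0)
    num_field = kernel_conv(arr * weighted)
    den_field = kernel_conv(weighted_sq)
    nb = G.shape[0]
    Gf = G.reshape(nb, -1)
    v = Gf @ num_field.ravel()
    A = (Gf * den_field.ravel()) @ Gf.T
    try:
        w = np.linalg.solve(A, v)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        w = np.linalg.solve(A + ridge * np.trace(A) / nb * np.eye(nb), v)
    return w


def eval_bias(model: BiasFieldModel) -> np.ndarray:
    """Evaluate ``b = sum_m w_m G_m`` on the pixel grid."""
    return np.tensordot(model.w, model.G, axes=1)


def estimate_bias(
    image,
    n_classes: int = 3,
    order: int = 3,
    kernel_sigma: float = 4.0,
    seed: int = 0,
    enhance_first: bool = False,
) -> tuple[np.ndarray, BiasFieldModel, np.ndarray]:
    """One-shot bias-field estimation from a tissue-classified image.

    Soft-clusters intensities, hard-assigns each pixel
    to its most likely tissue, and solves the weighted normal equations for
    the polynomial field that best explains the intensities as
    ``b(x) * c_class(x)``. With piecewise-constant tissue and an in-span
    bias this recovers the true field up to kernel smoothing (exactly, when
    the kernel is a delta). Returns ``(b, model, centers)`` with ``b``
    normalized to unit mean.

    The neighborhood enhancement is off by default here: the fit assumes
    the observation model ``image = b * c_class + noise``, which the
    nonlinear neighborhood filter distorts at tissue boundaries, while the
    clustering kernel already regularizes the fit against noise.
    """
    from . import enhancement, fuzzy_init
    from .levelset import KernelK

    img = image if hasattr(image, "pixels") else None
    arr = image.pixels if img is not None else np.asarray(image, dtype=float)
    if enhance_first:
        arr = enhancement.enhance(arr).pixels
    membership = fuzzy_init.fcm_cluster(arr, n_classes=n_classes, seed=seed)
    hard = np.argmax(membership.u, axis=0)
    M = np.stack([(hard == k).astype(float) for k in range(n_classes)])
    lam = np.ones_like(M)
    kernel = KernelK(kernel_sigma)
    G = legendre_basis(arr.shape[0], arr.shape[1], order)
    # alternate the bias solve with the center update until self-consistent;
    # a one-shot solve would fold center misestimates into the field
    c = membership.centers.copy()
    w = np.zeros(G.shape[0])
    for _ in range(100):
        w = solve_w(arr, lam, c, M, kernel.conv, G)
        b = np.tensordot(w, G, axes=1)
        scale = float(b.mean())
        if abs(scale) > 1e-12:
            b /= scale
            w /= scale
            c = c * scale
        kb = kernel.conv(b)
        kb2 = kernel.conv(b * b)
        c_new = (arr * M * kb).sum(axis=(1, 2)) / np.maximum((M * kb2).sum(axis=(1, 2)), 1e-300)
        if np.abs(c_new - c).max() < 1e-6:
            c = c_new
            break
        c = c_new
    return b, BiasFieldModel(G, w, order), c
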