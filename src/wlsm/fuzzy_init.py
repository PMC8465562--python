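"""Fuzzy c-means initialization and the per-pixel data-term weights.

Soft clustering of the (enhanced) image intensities supplies three things to
the level-set stage:

* initial cluster centers ``c``;
* initial level-set functions, via a hard argmax of the memberships;
* the per-pixel, per-class weights ``lambda_k = 1 - u_k**2`` that slow the
  contour down where class membership is already confident and speed it up
  near ambiguous (weak-boundary) pixels. Because memberships sum to one per
  pixel this weight is fully adaptive — it has no free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Image2D

__all__ = [
    "MembershipMatrix",
    "LevelSetState",
    "fcm_cluster",
    "lambda_from_membership",
    "init_levelsets",
    "LAMBDA_MIN",
]

#: lower clamp on lambda so fully confident pixels never stall the flow
LAMBDA_MIN = 1e-6


@dataclass
class MembershipMatrix:
    """Per-class, per-pixel fuzzy memberships ``u``, shape (K, H, W)."""

    u: np.ndarray
    centers: np.ndarray
    fuzzifier: float = 2.0
    converged: bool = True

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        if self.u.ndim != 3:
            raise ValueError("membership array must be (n_classes, H, W)")

    @property
    def n_classes(self) -> int:
        return self.u.shape[0]


@dataclass
class LevelSetState:
    """The pair (phi1, phi2) encoding three regions.

    Region memberships are ``M1 = 1 - H(phi1)``, ``M2 = H(phi1) H(phi2)``
    and ``M3 = H(phi1) (1 - H(phi2))`` for a smoothed Heaviside ``H``.
    """

    phi1: np.ndarray
    phi2: np.ndarray

    def __post_init__(self) -> None:
        self.phi1 = np.asarray(self.phi1, dtype=float)
        self.phi2 = np.asarray(self.phi2, dtype=float)
        if self.phi1.shape != self.phi2.shape:
            raise ValueError("phi1 and phi2 must share a shape")
        if not (np.all(np.isfinite(self.phi1)) and np.all(np.isfinite(self.phi2))):
            raise ValueError("level-set functions must be finite")

    def copy(self) -> "LevelSetState":
        return LevelSetState(self.phi1.copy(), self.phi2.copy())


def _as_array(image) -> np.ndarray:
    return image.pixels if isinstance(image, Image2D) else np.asarray(image, dtype=float)


def _fcm_memberships(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    dist = np.abs(x[None, :] - centers[:, None])  # (K, P)
    zero = dist < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = dist ** (-2.0 / (m - 1.0))
        u = inv / inv.sum(axis=0, keepdims=True)
    # exact-hit pixels get a one-hot membership
    hit = zero.any(axis=0)
    if hit.any():
        u[:, hit] = zero[:, hit] / zero[:, hit].sum(axis=0, keepdims=True)
    return u


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator,
                   sample: int = 4096) -> np.ndarray:
    xs = rng.choice(x, size=min(sample, x.size), replace=False)
    centers = [float(xs[rng.integers(xs.size)])]
    for _ in range(k - 1):
        d2 = np.min((xs[None, :] - np.array(centers)[:, None]) ** 2, axis=0)
        total = d2.sum()
        if total <= 0:
            centers.append(float(xs[rng.integers(xs.size)]))
            continue
        centers.append(float(xs[rng.choice(xs.size, p=d2 / total)]))
    return np.sort(np.array(centers))


def _fcm_run(x, centers, m, max_iter, tol):
    converged = False
    u = None
    for _ in range(max_iter):
        u = _fcm_memberships(x, centers, m)
        um = u**m
        new_centers = (um @ x) / um.sum(axis=1)
        if np.abs(new_centers - centers).max() < tol:
            centers = new_centers
            converged = True
            break
        centers = new_centers
    u = _fcm_memberships(x, centers, m)
    objective = float((u**m * (x[None, :] - centers[:, None]) ** 2).sum())
    return u, centers, objective, converged


def fcm_cluster(
    image,
    n_classes: int = 3,
    m: float = 2.0,
    max_iter: int = 300,
    tol: float = 1e-5,
    seed: int = 0,
    n_init: int = 5,
) -> MembershipMatrix:
    """Standard alternating fuzzy c-means on pixel intensities.

    The objective is non-convex, so the alternation is restarted from
    ``n_init`` center initializations — evenly spaced and extreme
    intensity quantiles plus seeded k-means++-style draws (which place
    centers in small but well-separated intensity modes) — and the run
    with the lowest objective wins. Deterministic for a given seed.
    ``converged=False`` flags a best run whose center update never
    dropped below ``tol`` within ``max_iter`` sweeps.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    arr = _as_array(image)
    x = arr.ravel()
    rng = np.random.default_rng(seed)
    q = (np.arange(n_classes) + 0.5) / n_classes
    inits = [np.quantile(x, q), np.quantile(x, np.linspace(0.02, 0.98, n_classes))]
    for _ in range(max(n_init - 2, 0)):
        inits.append(_kmeanspp_init(x, n_classes, rng))
    inits = inits[:n_init]
    best = None
    for centers0 in inits:
        u, centers, objective, converged = _fcm_run(x, centers0.copy(), m, max_iter, tol)
        if best is None or objective < best[2]:
            best = (u, centers, objective, converged)
    u, centers, _, converged = best
    u_img = u.reshape((n_classes,) + arr.shape)
    return MembershipMatrix(u_img, centers, fuzzifier=m, converged=converged)


def lambda_from_membership(membership: MembershipMatrix) -> np.ndarray:
    """Per-pixel data-term weights ``lambda_k = 1 - u_k**2 / sum_k u_k``.

    Since memberships sum to one per pixel this reduces to ``1 - u_k**2``.
    The raw value is 0 at a fully confident pixel; it is clamped below at
    ``LAMBDA_MIN`` so the data force never vanishes entirely.
    """
    u = membership.u
    lam = 1.0 - u**2 / u.sum(axis=0, keepdims=True)
    return np.clip(lam, LAMBDA_MIN, 1.0)


def init_levelsets(membership: MembershipMatrix, c0: float = 2.0) -> LevelSetState:
    """Binary-step level-set initialization from the fuzzy memberships.

    Pixels are hard-assigned by argmax over classes (ties break toward the
    lower class index, numpy's argmax rule). ``phi1`` is ``+c0`` on classes
    2 and 3 and ``-c0`` on class 1; ``phi2`` is ``+c0`` on class 2 and
    ``-c0`` elsewhere — consistent with the three-region membership
    products of :class:`LevelSetState`.
    """
    if membership.n_classes != 3:
        raise ValueError("level-set initialization requires exactly 3 classes")
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    hard = np.argmax(membership.u, axis=0)
    counts = np.bincount(hard.ravel(), minlength=3)
    if (counts == 0).any():
        raise ValueError("degenerate input: fewer than 3 nonempty classes")
    phi1 = np.where(hard == 0, -c0, c0)
    phi2 = np.where(hard == 1, c0, -c0)
    return LevelSetState(phi1.astype(float), phi2.astype(float))
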