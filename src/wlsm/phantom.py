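"""Synthetic brain-like phantoms with known truth, bias field and noise.

The generator emulates the corruption model of simulated-brain MRI
repositories: a piecewise-constant three-tissue image (CSF / GM / WM at
45 / 105 / 190 on the 0-255 scale), multiplied by a smooth positive
polynomial bias field of unit mean, plus additive Gaussian noise whose
standard deviation is a stated percentage of the brightest tissue mean
("5% noise" -> sigma = 0.05 * 190). The bias amplitude is expressed
peak-to-trough around the unit mean ("40% inhomogeneity" -> 0.4). All
randomness comes from one seed, so truth, bias and noise realization are
exactly reproducible.

Geometry is a nested-ellipse head: a GM ellipse on a CSF background with a
wiggly-boundary WM core, giving an interdigitated WM/GM interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bias_field import legendre_basis
from .io_formats import Image2D, LabelMap

__all__ = ["PhantomSpec", "make_phantom", "make_weak_boundary_phantom"]


@dataclass
class PhantomSpec:
    shape: tuple = (128, 128)
    #: mean intensities of (CSF, GM, WM) on the 0-255 scale
    intensities: tuple = (45.0, 105.0, 190.0)
    #: Gaussian sigma as a fraction of the brightest class mean
    noise_level: float = 0.05
    bias_order: int = 2
    #: peak-to-trough bias amplitude around the unit mean (0 -> flat field)
    bias_amplitude: float = 0.4
    #: Rician instead of additive Gaussian noise
    rician: bool = False
    seed: int = 0
    #: WM-GM contrast inside the weak-boundary band (gray levels)
    weak_gap: float = 15.0
    #: fraction of the image height covered by the weak-boundary band
    weak_band_frac: float = 0.35
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.bias_amplitude < 0 or self.bias_amplitude >= 2.0:
            raise ValueError("bias_amplitude must lie in [0, 2) to keep the field positive")
        if len(set(self.intensities)) != len(self.intensities):
            raise ValueError("class intensities must be distinct")


def _geometry(shape: tuple, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    yy, xx = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w), indexing="ij")
    labels = np.zeros(shape, dtype=np.int64)
    # GM ellipse on CSF background
    labels[(xx / 0.82) ** 2 + (yy / 0.72) ** 2 <= 1.0] = 1
    # WM core with a smooth random radial wiggle -> interdigitated interface
    theta = np.arctan2(yy, xx)
    n_lobes = int(rng.integers(4, 7))
    phase = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(0.08, 0.14)
    wiggle = 1.0 + amp * np.sin(n_lobes * theta + phase)
    r2 = (xx / (0.52 * wiggle)) ** 2 + (yy / (0.42 * wiggle)) ** 2
    labels[r2 <= 1.0] = 2
    return labels


def _bias(shape: tuple, order: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if amplitude == 0 or order == 0:
        return np.ones(shape)
    G = legendre_basis(shape[0], shape[1], order)
    coeff = rng.normal(size=G.shape[0])
    coeff[0] = 0.0  # no constant part; the mean is pinned at 1
    poly = np.tensordot(coeff, G, axes=1)
    ptp = poly.max() - poly.min()
    b = 1.0 + poly * (amplitude / ptp)
    return b / b.mean()


def make_phantom(spec: PhantomSpec | None = None) -> tuple[Image2D, LabelMap, Image2D]:
    """Generate (noisy image, truth labels, true bias field).

    ``image = clean * bias + noise`` clipped at zero, with
    ``sigma = noise_level * max(intensities)``.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    labels = _geometry(spec.shape, rng)
    clean = np.asarray(spec.intensities, dtype=float)[labels]
    bias = _bias(spec.shape, spec.bias_order, spec.bias_amplitude, rng)
    sigma = spec.noise_level * max(spec.intensities)
    signal = clean * bias
    if spec.rician:
        noisy = np.sqrt(
            (signal + rng.normal(0, sigma, spec.shape)) ** 2
            + rng.normal(0, sigma, spec.shape) ** 2
        )
    else:
        noisy = signal + rng.normal(0, sigma, spec.shape)
    image = Image2D(np.clip(noisy, 0.0, None), meta={"spec": "phantom", **spec.meta})
    return image, LabelMap(labels, 3), Image2D(bias)


def make_weak_boundary_phantom(spec: PhantomSpec | None = None) -> tuple[Image2D, LabelMap, Image2D]:
    """Phantom whose WM/GM contrast collapses inside a horizontal band.

    Within a band covering ``weak_band_frac`` of the image height the WM
    intensity is lowered to ``GM + weak_gap`` gray levels — below twice the
    noise sigma at the default settings — producing the low-contrast
    interdigitated boundary that defeats plain intensity thresholding.
    The realized contrast gap is recorded in the image metadata.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    labels = _geometry(spec.shape, rng)
    csf, gm, wm = spec.intensities
    clean = np.asarray(spec.intensities, dtype=float)[labels]
    h = spec.shape[0]
    half = int(round(0.5 * spec.weak_band_frac * h))
    band = np.zeros(spec.shape, dtype=bool)
    band[h // 2 - half : h // 2 + half, :] = True
    weak_wm = gm + spec.weak_gap
    clean = np.where(band & (labels == 2), weak_wm, clean)
    bias = _bias(spec.shape, spec.bias_order, spec.bias_amplitude, rng)
    sigma = spec.noise_level * max(spec.intensities)
    noisy = clean * bias + rng.normal(0, sigma, spec.shape)
    meta = {
        "spec": "weak-boundary phantom",
        "contrast_gap": float(weak_wm - gm),
        "noise_sigma": float(sigma),
        **spec.meta,
    }
    image = Image2D(np.clip(noisy, 0.0, None), meta=meta)
    return image, LabelMap(labels, 3), Image2D(bias)
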