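"""Image/label I/O and run configuration.

Conventions used throughout the package:

* pixel coordinates are row-major, 0-based, ``(row, col)`` order;
* intensities are rescaled to the [0, 255] range on load regardless of the
  source bit depth, because the default length-term weight ``nu`` is
  expressed in 255**2 units;
* NIfTI volumes are supported for 2-D slice extraction only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Image2D",
    "LabelMap",
    "RunConfig",
    "read_image",
    "read_labels",
    "write_result",
]

#: ITU-R BT.601 luminance weights, used when an RGB input is converted.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class Image2D:
    """A single-channel 2-D image with float intensities in [0, 255]."""

    pixels: np.ndarray
    source_path: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 3 or self.pixels.shape[1] < 3:
            raise ValueError("image must be at least 3x3 (neighborhood operators need a 3x3 window)")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if self.pixels.min() < 0:
            raise ValueError("image contains negative intensities")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMap:
    """Integer class labels, one per pixel, values in {0, ..., n_classes-1}."""

    labels: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.array_equal(self.labels, np.round(self.labels)):
                raise ValueError("labels must be integers")
            self.labels = self.labels.astype(np.int64)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if self.n_classes < 1:
            raise ValueError("n_classes must be positive")
        if self.labels.min() < 0 or self.labels.max() >= self.n_classes:
            raise ValueError("labels out of range for n_classes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class RunConfig:
    """All tunable parameters of the segmentation pipeline.

    Defaults follow the fixed settings used for brain MRI on the 0-255
    intensity scale: ``nu = 0.001 * 255**2`` (length term), ``mu = 1``
    (distance regularizer), ``dt = 0.1`` (explicit Euler step), and a
    convergence rule that stops when the cluster centers move by less than
    ``conv_tol = 0.001`` between outer iterations.
    """

    n_classes: int = 3
    nu: float = 0.001 * 255.0 * 255.0
    mu: float = 1.0
    dt: float = 0.1
    #: smoothing width of the regularized Heaviside/Dirac pair
    heaviside_eps: float = 1.0
    #: neighborhood radius of the enhancement operator (1 -> 3x3 window)
    window_radius: int = 1
    #: Laplace-kernel bandwidth l applied to the local variation coefficient
    laplace_bandwidth: float = 1.0
    #: total degree of the Legendre bias-field basis
    legendre_order: int = 3
    #: std of the truncated Gaussian clustering kernel K (radius = 2 sigma)
    kernel_sigma: float = 4.0
    fcm_fuzzifier: float = 2.0
    fcm_max_iter: int = 300
    fcm_tol: float = 1e-5
    #: magnitude of the binary-step level-set initialization
    c0: float = 2.0
    #: saturation bound on |phi|; the arctan Heaviside is flat beyond it
    phi_max: float = 30.0
    max_iters: int = 500
    conv_tol: float = 0.001
    seed: int = 0
    #: skip the neighborhood enhancement stage if False
    enhance: bool = True

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.mu <= 0 or self.dt <= 0 or self.conv_tol <= 0:
            raise ValueError("nu, mu, dt and conv_tol must all be positive")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.laplace_bandwidth <= 0:
            raise ValueError("laplace_bandwidth must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rescale_255(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        return (arr - lo) * (255.0 / (hi - lo))
    return np.zeros_like(arr)


def read_image(
    path: str | Path,
    *,
    slice_axis: int = 2,
    slice_index: int | None = None,
    rescale: bool = True,
    rgb_to_gray: bool = False,
) -> Image2D:
    """Read a grayscale slice from PNG/TIFF or a NIfTI volume.

    NIfTI inputs require ``slice_index``; the 2-D slice is taken
    perpendicular to ``slice_axis`` (0/1/2, default axial for an
    RAS-oriented volume). Multi-channel rasters are rejected unless
    ``rgb_to_gray`` requests BT.601 luminance conversion. With ``rescale``
    (default) intensities are mapped onto [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = nib.load(str(path))
        data = np.asanyarray(vol.dataobj)
        if data.ndim == 2:
            arr = data
        elif data.ndim == 3:
            if slice_index is None:
                raise ValueError("NIfTI volume requires slice_index")
            arr = np.take(data, slice_index, axis=slice_axis)
            meta["slice_axis"] = slice_axis
            meta["slice_index"] = slice_index
            meta["orientation"] = "".join(nib.aff2axcodes(vol.affine))
        else:
            raise ValueError(f"cannot extract a 2-D slice from shape {data.shape}")
    else:
        arr = iio.imread(path)
        if arr.ndim == 3:
            if not rgb_to_gray:
                raise ValueError(
                    "multi-channel image; pass rgb_to_gray=True for BT.601 luminance conversion"
                )
            arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image after slicing, got shape {arr.shape}")
    arr = np.asarray(arr, dtype=float)
    if rescale:
        arr = _rescale_255(arr)
    elif arr.min() < 0:
        arr = arr - arr.min()
    return Image2D(arr, source_path=str(path), meta=meta)


def read_labels(path: str | Path, n_classes: int | None = None) -> LabelMap:
    """Read an integer label map from a PNG (one integer per class)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        raise ValueError("label maps must be single-channel")
    labels = arr.astype(np.int64)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    return LabelMap(labels, n_classes)


def write_result(result, out_dir: str | Path) -> list[Path]:
    """Write a :class:`~wlsm.levelset.SegmentationResult` to ``out_dir``.

    Produces ``labels.png`` (uint8, one integer per class), 16-bit PNGs of
    the estimated bias field and bias-corrected image, ``energy_trace.csv``
    (one row per completed iteration) and ``run.json`` with the
    configuration and convergence information.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out_dir / "labels.png"
    iio.imwrite(p, result.labels.labels.astype(np.uint8))
    written.append(p)

    for name, img in [("bias_field", result.bias), ("corrected", result.corrected)]:
        p = out_dir / f"{name}.png"
        iio.imwrite(p, _to_uint16(img.pixels))
        written.append(p)

    p = out_dir / "energy_trace.csv"
    with open(p, "w") as fh:
        fh.write("iteration,F,data,length,penalty," +
                 ",".join(f"c{k}" for k in range(len(result.centers))) + "\n")
        for i, row in enumerate(result.trace.rows()):
            fh.write(f"{i}," + ",".join(f"{v:.10g}" for v in row) + "\n")
    written.append(p)

    p = out_dir / "run.json"
    payload = {
        "config": result.config.to_dict() if result.config is not None else None,
        "converged": bool(result.converged),
        "iterations": int(result.iterations),
        "centers": [float(c) for c in result.centers],
        "bias_coefficients": [float(v) for v in result.w],
    }
    with open(p, "w") as fh:
        json.dump(payload, fh, indent=2)
    written.append(p)
    return written


def _to_uint16(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        scaled = (arr - lo) / (hi - lo)
    else:
        scaled = np.zeros_like(arr)
    return np.round(scaled * 65535).astype(np.uint16)
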