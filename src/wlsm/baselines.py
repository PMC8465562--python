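"""Plain intensity-only baselines used for comparison runs.

These deliberately ignore spatial context and bias: they are the reference
points against which the value of enhancement, fuzzy spatial constraints
and bias-field estimation is measured.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.vq import kmeans2

from .io_formats import Image2D, LabelMap

__all__ = ["kmeans_threshold", "otsu_threshold"]


def _as_array(image) -> np.ndarray:
    return image.pixels if isinstance(image, Image2D) else np.asarray(image, dtype=float)


def kmeans_threshold(image, n_classes: int = 3) -> LabelMap:
    """Hard k-means on raw intensities, centers initialized at quantiles."""
    arr = _as_array(image)
    x = arr.ravel()
    q = (np.arange(n_classes) + 0.5) / n_classes
    init = np.quantile(x, q)
    _, labels = kmeans2(x, init, minit="matrix")
    return LabelMap(labels.reshape(arr.shape).astype(np.int64), n_classes)


def otsu_threshold(image, n_classes: int = 3) -> LabelMap:
    """Multi-level Otsu thresholding of raw intensities."""
    from skimage.filters import threshold_multiotsu

    arr = _as_array(image)
    th = threshold_multiotsu(arr, classes=n_classes)
    return LabelMap(np.digitize(arr, th).astype(np.int64), n_classes)
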