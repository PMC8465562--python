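"""Segmentation scoring: accuracy (SA) and Jaccard similarity (JSC).

SA over a class subset is the number of correctly labeled pixels of those
classes divided by the number of truth pixels of those classes; JSC is
intersection-over-union of one class mask. Model class labels are
arbitrary, so scoring first aligns them to the truth labels by the
overlap-maximizing permutation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .io_formats import LabelMap

__all__ = ["ScoreReport", "sa", "jsc", "match_labels", "score"]


@dataclass
class ScoreReport:
    sa_selected: float
    sa_all: float
    jsc_per_class: dict
    permutation: tuple
    selected_classes: tuple


def _as_labels(x) -> np.ndarray:
    return x.labels if isinstance(x, LabelMap) else np.asarray(x)


def sa(pred, truth, classes=None) -> float:
    """Segmentation accuracy over ``classes`` (default: all classes).

    ``sum_i |S_i ∩ G_i| / sum_j |G_j|`` — assumes labels are already
    aligned (see :func:`match_labels`).
    """
    p = _as_labels(pred)
    g = _as_labels(truth)
    if p.shape != g.shape:
        raise ValueError("prediction and truth must share a shape")
    if classes is None:
        classes = np.unique(g)
    classes = np.asarray(list(classes))
    correct = 0
    total = 0
    for k in classes:
        gk = g == k
        correct += int(np.count_nonzero(gk & (p == k)))
        total += int(np.count_nonzero(gk))
    if total == 0:
        raise ValueError("no truth pixels in the selected classes")
    return correct / total


def jsc(pred, truth, class_id: int) -> float:
    """Jaccard similarity |S ∩ G| / |S ∪ G| for one class mask.

    Defined as 1.0 when the class is absent from both maps.
    """
    p = _as_labels(pred) == class_id
    g = _as_labels(truth) == class_id
    union = int(np.count_nonzero(p | g))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(p & g)) / union


def match_labels(pred, truth, n_classes: int | None = None) -> tuple:
    """Permutation of predicted labels maximizing total overlap with truth.

    Exhaustive over k! permutations (k <= 5 in practice). Returns a tuple
    ``perm`` such that predicted label ``j`` should be read as truth label
    ``perm[j]``.
    """
    p = _as_labels(pred)
    g = _as_labels(truth)
    if n_classes is None:
        n_classes = int(max(p.max(), g.max())) + 1
    if n_classes > 5:
        raise ValueError("exhaustive matching is limited to 5 classes")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    for j in range(n_classes):
        pj = p == j
        for k in range(n_classes):
            counts[j, k] = np.count_nonzero(pj & (g == k))
    best, best_overlap = None, -1
    for perm in itertools.permutations(range(n_classes)):
        overlap = sum(counts[j, perm[j]] for j in range(n_classes))
        if overlap > best_overlap:
            best, best_overlap = perm, overlap
    return best


def apply_permutation(pred, perm) -> np.ndarray:
    p = _as_labels(pred)
    return np.asarray(perm)[p]


def score(pred, truth, n_classes: int | None = None, selected=None) -> ScoreReport:
    """Full report: label matching, SA over selected classes, per-class JSC.

    ``selected`` defaults to all classes except 0 — the darkest class
    (CSF/background) is customarily excluded so the score reflects the
    WM/GM tissue boundaries.
    """
    g = _as_labels(truth)
    if n_classes is None:
        n_classes = int(max(_as_labels(pred).max(), g.max())) + 1
    perm = match_labels(pred, truth, n_classes)
    aligned = apply_permutation(pred, perm)
    if selected is None:
        selected = tuple(range(1, n_classes))
    return ScoreReport(
        sa_selected=sa(aligned, g, selected),
        sa_all=sa(aligned, g, None),
        jsc_per_class={int(k): jsc(aligned, g, k) for k in range(n_classes)},
        permutation=perm,
        selected_classes=tuple(selected),
    )
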