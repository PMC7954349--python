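"""Class separability via the sign-reversed generalized discrimination value.

The generalized discrimination value (GDV) compares mean within-class to mean
between-class pairwise Euclidean distances after per-dimension z-scoring and
a 1/sqrt(D) dimensionality normalization.  Reported sign-reversed, it is 0 in
expectation for classes drawn from one distribution and exactly 1 for two
equal-sized classes each collapsed to a single point that differs in every
dimension — the two anchor values that pin the convention used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = ["GDVResult", "gdv"]


@dataclass
class GDVResult:
    """Sign-reversed GDV plus the per-class distance summaries behind it."""

    value: float
    n_dimensions: int
    n_classes: int
    intra_class: dict  # class -> mean within-class pairwise distance
    inter_class: dict  # (class, class) -> mean cross-class pairwise distance


def gdv(points: np.ndarray, classes) -> GDVResult:
    """Sign-reversed generalized discrimination value of labelled points.

    Procedure: (1) z-score every dimension over all points (population SD;
    a zero-variance dimension becomes all zeros), (2) scale all values by
    0.5, (3) take the mean Euclidean distance over distinct within-class
    pairs for each class and over all cross pairs for each class pair,
    (4) GDV = (1/sqrt(D)) * [mean of within-class means - mean of
    cross-class means], (5) return -GDV, so larger is more separable.
    """
    X = np.asarray(points, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("points must be an (n, D) matrix with D >= 1")
    labels = np.asarray(classes)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("one class label per point required")
    uniq = np.unique(labels)
    L = uniq.size
    if L < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int(np.sum(labels == c)) for c in uniq}
    small = [c for c, k in counts.items() if k < 2]
    if small:
        raise ValueError(f"every class needs >= 2 points; too small: {small}")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD
    Z = np.zeros_like(X)
    nz = sd > 0
    Z[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    Z *= 0.5

    D = X.shape[1]
    intra = {}
    for c in uniq:
        pts = Z[labels == c]
        intra[c] = float(pdist(pts).mean())
    inter = {}
    for i in range(L):
        for j in range(i + 1, L):
            a, b = uniq[i], uniq[j]
            inter[(a, b)] = float(cdist(Z[labels == a], Z[labels == b]).mean())

    mean_intra = np.mean(list(intra.values()))
    mean_inter = np.mean(list(inter.values()))
    value = -((mean_intra - mean_inter) / np.sqrt(D))
    return GDVResult(value=float(value), n_dimensions=D, n_classes=L,
                     intra_class=intra, inter_class=inter)
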