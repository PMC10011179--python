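"""Multi-class ReliefF feature weighting.

Weights estimate how well each feature separates near neighbours of
different classes: for every sample, the k nearest same-class hits pull
a feature's weight down by their mean per-feature difference, and the k
nearest misses of every other class push it up, weighted by the class
prior P(c)/(1 - P(class(anchor))).  Features are min-max scaled first so
differences are commensurate; zero-range (constant) features contribute
nothing.  Every sample serves as an anchor.

The EW band image whose spectra earn the highest ReliefF weight is the
*reference image* of the reflectance-image set.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["ReliefF", "relieff_weights"]


def relieff_weights(X: np.ndarray, y: np.ndarray, k_neighbors: int = 10) -> np.ndarray:
    """ReliefF weights per feature (higher = more class-discriminative)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    classes, counts = np.unique(y, return_counts=True)
    min_count = counts.min()
    if k_neighbors > min_count - 1:
        raise ValueError(
            f"k_neighbors={k_neighbors} exceeds smallest class size minus one ({min_count - 1})"
        )
    rng_span = X.max(axis=0) - X.min(axis=0)
    scale = np.where(rng_span > 0, rng_span, 1.0)
    Z = (X - X.min(axis=0)) / scale
    Z[:, rng_span == 0] = 0.0  # constant features: zero contribution

    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    # pairwise Manhattan distances on the scaled features
    dist = np.abs(Z[:, None, :] - Z[None, :, :]).sum(axis=2)
    np.fill_diagonal(dist, np.inf)

    W = np.zeros(d)
    for i in range(n):
        ci = y[i]
        hits = np.flatnonzero(y == ci)
        hits = hits[hits != i]
        hit_order = hits[np.argsort(dist[i, hits], kind="stable")][:k_neighbors]
        W -= np.abs(Z[hit_order] - Z[i]).mean(axis=0)
        for c in classes:
            if c == ci:
                continue
            miss = np.flatnonzero(y == c)
            miss_order = miss[np.argsort(dist[i, miss], kind="stable")][:k_neighbors]
            w_c = priors[c] / (1.0 - priors[ci])
            W += w_c * np.abs(Z[miss_order] - Z[i]).mean(axis=0)
    return W / n


class ReliefF(BaseEstimator):
    """Scikit-learn-style wrapper; ``feature_importances_`` after fit."""

    def __init__(self, k_neighbors: int = 10):
        self.k_neighbors = k_neighbors

    def fit(self, X: np.ndarray, y: np.ndarray):
        self.feature_importances_ = relieff_weights(X, y, self.k_neighbors)
        self.top_feature_ = int(np.argmax(self.feature_importances_))
        return self
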