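"""Gaussian kernels between sample views."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist, pdist


def gaussian_kernel(X1: np.ndarray, X2: np.ndarray, sigma: float) -> np.ndarray:
    """K[i, j] = exp(-||x1_i - x2_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("feature dimensions do not match")
    sq = cdist(X1, X2, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma ** 2))


def median_sigma(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance — the default kernel width."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        return 1.0
    d = pdist(X, metric="euclidean")
    med = float(np.median(d))
    return med if med > 0 else 1.0
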