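"""Exact sup over grid pairs of the weighted-increment functional.

Both the cusum-type monitoring statistic and the Monte-Carlo limit for its
limiting distribution need ``max_{1<=i<j<=k} ||(i/j) W_j - W_i||`` for a
d-dimensional path W indexed 1..k.  The scan is O(k^2) but vectorised over
the inner index, which is exact and fast enough for horizons of a few
thousand.
"""

from __future__ import annotations

import numpy as np


def pairwise_weighted_sup(w: np.ndarray) -> float:
    """``max_{i<j} ||(i/j) w_j - w_i||_2`` for a (k, d) path (rows = times 1..k)."""
    return float(pairwise_weighted_path(w)[-1])


def pairwise_weighted_path(w: np.ndarray) -> np.ndarray:
    """Running maxima: entry k-1 is the sup over pairs with j <= k (0 when k < 2)."""
    w = np.atleast_2d(np.asarray(w, dtype=float))
    k = w.shape[0]
    path = np.zeros(k)
    best = 0.0
    for j in range(1, k):
        ratio = np.arange(1, j + 1) / (j + 1.0)
        diff = ratio[:, None] * w[j] - w[:j]
        best = max(best, float((diff * diff).sum(axis=1).max()))
        path[j] = best
    return np.sqrt(path)
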