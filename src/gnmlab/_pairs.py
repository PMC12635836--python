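"""Condensed upper-triangle pair indexing shared across modules.

All pairwise quantities (distances, wiring weights, connection
probabilities) are stored as 1-D arrays over the n*(n-1)/2 unordered node
pairs, in the same order as :func:`scipy.spatial.distance.pdist` /
``numpy.triu_indices``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=64)
def triu_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle of an n x n matrix."""
    iu = np.triu_indices(n, 1)
    return iu[0].copy(), iu[1].copy()


def n_pairs(n: int) -> int:
    return n * (n - 1) // 2


def condense(mat: np.ndarray) -> np.ndarray:
    """Extract the strict upper triangle of a square matrix as a 1-D array."""
    i, j = triu_pairs(mat.shape[0])
    return np.asarray(mat)[i, j]


def square(vec: np.ndarray, n: int, dtype=None) -> np.ndarray:
    """Inverse of :func:`condense`: symmetric matrix with a zero diagonal."""
    out = np.zeros((n, n), dtype=dtype if dtype is not None else np.asarray(vec).dtype)
    i, j = triu_pairs(n)
    out[i, j] = vec
    out[j, i] = vec
    return out


def pair_index(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    """Condensed index of unordered pairs (i, j), i != j, 0-based."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    if np.any(lo == hi):
        raise ValueError("self-pairs have no condensed index")
    return lo * (2 * n - lo - 3) // 2 + hi - 1
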