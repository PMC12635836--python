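"""Binary undirected networks with a fixed node order."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._pairs import condense, pair_index, square, triu_pairs

__all__ = ["BinaryNetwork"]


@dataclass
class BinaryNetwork:
    """Undirected, hollow, symmetric 0/1 adjacency matrix.

    Node order is positional and must match the embedding used alongside.
    """

    A: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must be hollow (zero diagonal)")
        self.A = A.astype(np.int8)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return int(self.A.sum()) // 2

    @property
    def degree(self) -> np.ndarray:
        return self.A.sum(axis=1).astype(np.int64)

    def edges(self) -> np.ndarray:
        """``(m, 2)`` array of edges with i < j, lexicographic order."""
        i, j = np.nonzero(np.triu(self.A, 1))
        return np.column_stack([i, j])

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(map(tuple, self.edges()))

    def condensed(self) -> np.ndarray:
        """Boolean presence over unordered pairs, pdist order."""
        return condense(self.A).astype(bool)

    def edge_pair_indices(self) -> np.ndarray:
        """Condensed pair indices of the present edges (sorted)."""
        return np.flatnonzero(self.condensed())

    @classmethod
    def empty(cls, n: int) -> "BinaryNetwork":
        return cls(np.zeros((n, n), dtype=np.int8))

    @classmethod
    def from_edges(cls, n: int, edges) -> "BinaryNetwork":
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        A = np.zeros((n, n), dtype=np.int8)
        if edges.size:
            if edges.min() < 0 or edges.max() >= n:
                raise ValueError("edge references a node outside 0..n-1")
            A[edges[:, 0], edges[:, 1]] = 1
            A[edges[:, 1], edges[:, 0]] = 1
        return cls(A)

    @classmethod
    def from_pair_indices(cls, n: int, idx) -> "BinaryNetwork":
        vec = np.zeros(len(triu_pairs(n)[0]), dtype=np.int8)
        vec[np.asarray(idx, dtype=np.int64)] = 1
        return cls(square(vec, n))

    def edge_lengths(self, D: np.ndarray) -> np.ndarray:
        e = self.edges()
        return np.asarray(D)[e[:, 0], e[:, 1]]

    def __eq__(self, other) -> bool:  # type: ignore[override]
        return isinstance(other, BinaryNetwork) and np.array_equal(self.A, other.A)

    def overlap(self, other: "BinaryNetwork") -> float:
        """Fraction of this network's edges also present in ``other``."""
        if self.m == 0:
            raise ValueError("overlap undefined for an edgeless network")
        inter = int(np.logical_and(self.A, other.A).sum()) // 2
        return inter / self.m


def pair_indices_of_edges(edges: np.ndarray, n: int) -> np.ndarray:
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    return pair_index(edges[:, 0], edges[:, 1], n)
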