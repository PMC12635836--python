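"""Spatial embeddings: node coordinates, wiring costs, and surface adjacency.

A :class:`SpatialEmbedding` carries everything the wiring rules and the
distance-resolved diagnostics need to know about geometry: node labels,
3-D coordinates in millimetres, the pairwise Euclidean wiring-cost matrix
``D``, and a sparse "surface adjacency" graph used only for the
neighbour-smoothing feature generator.

Real connectome studies approximate wiring cost by interregional Euclidean
distance; this module does the same for synthetic embeddings, with the node
centroid standing in for a parcel's surface vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from ._pairs import condense

__all__ = ["SpatialEmbedding", "make_embedding"]


@dataclass
class SpatialEmbedding:
    """Node coordinates plus the derived wiring-cost matrix.

    Parameters
    ----------
    node_ids
        Ordered node labels; positions define the node order used by every
        adjacency matrix in the package.
    coords
        ``(n, 3)`` array of coordinates, mm.
    D
        ``(n, n)`` symmetric Euclidean distance matrix, mm, zero diagonal.
    neighbor_graph
        ``(n, n)`` symmetric hollow 0/1 matrix: which nodes count as
        "adjacent on the surface" for feature smoothing. Must be connected.
    """

    node_ids: list[str]
    coords: np.ndarray
    D: np.ndarray
    neighbor_graph: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.node_ids)
        if self.coords.shape[0] != n or self.D.shape != (n, n):
            raise ValueError("node_ids, coords and D disagree on node count")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("D must be symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("D must have a zero diagonal")
        off = condense(self.D)
        if np.any(off <= 0):
            raise ValueError("degenerate geometry: zero off-diagonal distance "
                             "(duplicate coordinates?)")
        if self.neighbor_graph is not None:
            g = np.asarray(self.neighbor_graph)
            if g.shape != (n, n) or not np.array_equal(g, g.T):
                raise ValueError("neighbor_graph must be a symmetric n x n matrix")
            if np.any(np.diag(g) != 0):
                raise ValueError("neighbor_graph must be hollow")

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def d_condensed(self) -> np.ndarray:
        """Pairwise distances over unordered pairs, pdist order."""
        return condense(self.D)

    @classmethod
    def from_coords(cls, coords: np.ndarray, node_ids: list[str] | None = None,
                    neighbor_k: int | None = 6, **meta) -> "SpatialEmbedding":
        coords = np.asarray(coords, dtype=float)
        n = coords.shape[0]
        if node_ids is None:
            node_ids = [f"node{i}" for i in range(n)]
        D = squareform(pdist(coords))
        g = _knn_graph(coords, neighbor_k) if neighbor_k else None
        return cls(node_ids=list(node_ids), coords=coords, D=D,
                   neighbor_graph=g, meta=dict(meta))


def _knn_graph(coords: np.ndarray, k: int) -> np.ndarray:
    """Union-symmetrised k-nearest-neighbour graph, augmented to be connected."""
    n = coords.shape[0]
    k = min(k, n - 1)
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)  # first hit is the node itself
    g = np.zeros((n, n), dtype=np.int8)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    g[rows, cols] = 1
    g = np.maximum(g, g.T)
    # stitch disconnected components together via their closest node pair
    while True:
        ncomp, labels = connected_components(g, directed=False)
        if ncomp == 1:
            break
        a = np.flatnonzero(labels == labels[0])
        b = np.flatnonzero(labels != labels[0])
        d = np.linalg.norm(coords[a][:, None, :] - coords[b][None, :, :], axis=-1)
        ia, ib = np.unravel_index(np.argmin(d), d.shape)
        g[a[ia], b[ib]] = g[b[ib], a[ia]] = 1
    return g


def make_embedding(n: int, geometry: str = "shell", scale: float = 100.0,
                   seed: int | None = None, neighbor_k: int = 6) -> SpatialEmbedding:
    """Generate a random spatial embedding of ``n`` nodes.

    Geometries
    ----------
    ``shell``
        Uniform points on a hemispheric shell of radius ``scale`` mm — a
        rough stand-in for a cortical hemisphere.
    ``sheet``
        Uniform points on a ``scale`` x ``scale`` mm square (z = 0).
    ``cloud``
        Uniform points in a ``scale``-mm cube.
    """
    if n < 2:
        raise ValueError("need at least two nodes")
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    if geometry == "shell":
        # uniform on the unit sphere restricted to z >= 0
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        v[:, 2] = np.abs(v[:, 2])
        coords = v * scale
    elif geometry == "sheet":
        coords = np.column_stack([rng.uniform(0, scale, size=(n, 2)),
                                  np.zeros(n)])
    elif geometry == "cloud":
        coords = rng.uniform(0, scale, size=(n, 3))
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    emb = SpatialEmbedding.from_coords(
        coords, neighbor_k=neighbor_k,
        geometry=geometry, scale=scale, seed=seed)
    return emb
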