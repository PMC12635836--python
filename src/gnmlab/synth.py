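"""Synthetic targets, cohorts, and spatially autocorrelated nodal features.

This module builds everything a desk-scale study of generative network
models needs without external data:

* spatially embedded binary target networks with an exponential
  distance-decay in connection probability and, optionally, a planted set
  of long-range inter-hub edges — the property real connectomes have and
  distance-penalised growth models systematically miss;
* cohorts of perturbed "individual" networks with controlled edge overlap,
  obtained by length-matched edge relocations;
* random spatially autocorrelated nodal features, generated by iterated
  neighbour averaging, and their interregional similarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._pairs import condense, triu_pairs
from .embedding import SpatialEmbedding
from .network import BinaryNetwork
from .rewiring import RewiringConfig, rewire_partial

__all__ = ["FeatureTable", "SimilarityMatrix", "PlantedTarget",
           "smooth_random_features", "feature_similarity", "plant_target",
           "make_cohort"]


@dataclass
class FeatureTable:
    """Node x feature real matrix with generation provenance."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class SimilarityMatrix:
    """Symmetric node x node matrix in [0, 1].

    ``orientation`` records whether large values mean similar
    (``"similarity"``) or dissimilar (``"distance"``) node pairs; the
    diagonal is not used by any consumer.
    """

    F: np.ndarray
    orientation: str = "similarity"

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if not np.allclose(F, F.T):
            raise ValueError("similarity matrix must be symmetric")
        off = condense(F)
        if off.min() < -1e-12 or off.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        self.F = np.clip(F, 0.0, 1.0)

    def flipped(self) -> "SimilarityMatrix":
        other = "distance" if self.orientation == "similarity" else "similarity"
        return SimilarityMatrix(1.0 - self.F, orientation=other)


@dataclass
class PlantedTarget:
    """A synthetic target network plus its construction bookkeeping."""

    network: BinaryNetwork
    planted_long_edges: np.ndarray   # (n_planted, 2)
    hub_nodes: np.ndarray
    decay: float                     # lambda, 1/mm

    @property
    def n_planted(self) -> int:
        return self.planted_long_edges.shape[0]


def smooth_random_features(embedding: SpatialEmbedding, n_features: int = 20,
                           n_smooth: int = 5, seed: int | None = None,
                           init: np.ndarray | None = None) -> FeatureTable:
    """Random spatially autocorrelated features by neighbour averaging.

    Each feature starts as an independent uniform [0, 1] draw per node.
    Then, for ``n_smooth`` rounds, every node's value is replaced by the
    mean of its surface-adjacent neighbours' values, synchronously (all
    means are computed from the pre-round state before any update).

    ``init`` bypasses the random initialisation (testing hook for
    degenerate starting columns).
    """
    g = embedding.neighbor_graph
    if g is None:
        raise ValueError("embedding has no neighbor_graph")
    g = np.asarray(g, dtype=float)
    deg = g.sum(axis=1)
    if np.any(deg == 0):
        bad = int(np.flatnonzero(deg == 0)[0])
        raise ValueError(f"node {bad} is isolated in the neighbor graph; "
                         "neighbour mean undefined")
    rng = np.random.default_rng(seed)
    if init is not None:
        v = np.asarray(init, dtype=float).copy()
        if v.shape[0] != embedding.n:
            raise ValueError("init has wrong node count")
        if v.ndim == 1:
            v = v[:, None]
    else:
        v = rng.uniform(0.0, 1.0, size=(embedding.n, n_features))
    w = g / deg[:, None]              # row-stochastic neighbour averaging
    for _ in range(n_smooth):
        v = w @ v
    return FeatureTable(values=v, provenance={
        "n_features": int(v.shape[1]), "n_smooth": int(n_smooth),
        "seed": seed, "generator": "neighbor-smoothing"})


def feature_similarity(features: FeatureTable,
                       orientation: str = "similarity") -> SimilarityMatrix:
    """Interregional similarity: Pearson correlation of node profiles.

    Each node's profile is its row over the feature columns. The raw
    correlation r in [-1, 1] is mapped to the unit interval; with the
    default ``similarity`` orientation F = (r + 1)/2, so anticorrelated
    pairs score 0 and identical profiles score 1. ``distance`` gives the
    literal rescaled Pearson distance, F = (1 - r)/2 = 1 - similarity.
    """
    v = np.asarray(features.values, dtype=float)
    if v.shape[1] < 2:
        raise ValueError("need at least two features per node profile")
    sd = v.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"node {bad} has a zero-variance feature profile; "
                         "correlation undefined")
    r = np.corrcoef(v)
    r = np.clip(r, -1.0, 1.0)
    if orientation == "similarity":
        F = (r + 1.0) / 2.0
    elif orientation == "distance":
        F = (1.0 - r) / 2.0
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return SimilarityMatrix(F=F, orientation=orientation)


def _farthest_point_hubs(coords: np.ndarray, n_hubs: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Spatially dispersed hub nodes by farthest-point sampling."""
    n = coords.shape[0]
    hubs = [int(rng.integers(n))]
    d_min = np.linalg.norm(coords - coords[hubs[0]], axis=1)
    while len(hubs) < n_hubs:
        nxt = int(np.argmax(d_min))
        hubs.append(nxt)
        d_min = np.minimum(d_min, np.linalg.norm(coords - coords[nxt], axis=1))
    return np.asarray(sorted(hubs), dtype=np.int64)


def plant_target(embedding: SpatialEmbedding, m: int, decay: float = 0.0,
                 hub_spec: dict | None = None,
                 seed: int | None = None) -> PlantedTarget:
    """Distance-decayed random network with planted long-range hub edges.

    Parameters
    ----------
    m
        Total edge count (exact).
    decay
        Exponential decay rate lambda (1/mm): absent pairs are sampled
        without replacement with probability proportional to
        exp(-lambda * D_ij). Zero gives a uniform random graph.
    hub_spec
        ``{"n_hubs": int, "long_cutoff": float (mm), "n_planted": int}``.
        ``n_planted`` inter-hub pairs with length >= ``long_cutoff`` are
        planted before the distance-decayed fill. ``None`` plants nothing.
    """
    n = embedding.n
    d = embedding.d_condensed
    q = d.size
    if m > q:
        raise ValueError(f"m={m} exceeds the {q} available pairs")
    rng = np.random.default_rng(seed)
    iu_i, iu_j = triu_pairs(n)

    planted = np.empty((0, 2), dtype=np.int64)
    hubs = np.empty(0, dtype=np.int64)
    planted_idx = np.empty(0, dtype=np.int64)
    if hub_spec:
        n_hubs = int(hub_spec["n_hubs"])
        cutoff = float(hub_spec["long_cutoff"])
        n_planted = int(hub_spec["n_planted"])
        if n_planted > m:
            raise ValueError("n_planted exceeds total edge count m")
        hubs = _farthest_point_hubs(embedding.coords, n_hubs, rng)
        is_hub = np.zeros(n, dtype=bool)
        is_hub[hubs] = True
        cand = np.flatnonzero(is_hub[iu_i] & is_hub[iu_j] & (d >= cutoff))
        if cand.size < n_planted:
            raise ValueError(
                f"infeasible hub_spec: only {cand.size} inter-hub pairs "
                f"beyond {cutoff} mm, {n_planted} requested")
        planted_idx = rng.choice(cand, size=n_planted, replace=False)
        planted = np.column_stack([iu_i[planted_idx], iu_j[planted_idx]])

    remaining = m - planted_idx.size
    free = np.ones(q, dtype=bool)
    free[planted_idx] = False
    free_idx = np.flatnonzero(free)
    # sampling without replacement proportional to exp(-lambda d):
    # exponential-race keys
    w = np.exp(-decay * (d[free_idx] - d[free_idx].min()))
    keys = rng.exponential(size=free_idx.size) / w
    fill = free_idx[np.argpartition(keys, remaining - 1)[:remaining]] \
        if remaining else np.empty(0, dtype=np.int64)

    all_idx = np.concatenate([planted_idx, fill])
    net = BinaryNetwork.from_pair_indices(n, all_idx)
    return PlantedTarget(network=net, planted_long_edges=planted,
                         hub_nodes=hubs, decay=float(decay))


def make_cohort(base: BinaryNetwork, embedding: SpatialEmbedding,
                n_subjects: int, n_swaps: int,
                seed: int | None = None) -> list[BinaryNetwork]:
    """Cohort of "individual" networks: length-matched edge relocations.

    Every subject is the base network with ``n_swaps`` edges relocated to
    originally-absent pairs of similar length, so all subjects share the
    base's density and each retains exactly (m - n_swaps)/m of its edges.
    """
    if n_swaps > base.m:
        raise ValueError("n_swaps exceeds the base edge count")
    ss = np.random.SeedSequence(seed)
    cfg = RewiringConfig(ordering="random", target_rule="similar")
    out = []
    for child in ss.spawn(n_subjects):
        s = int(child.generate_state(1)[0] % (2 ** 31))
        out.append(rewire_partial(base, embedding, n_swaps, seed=s, config=cfg))
    return out
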