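"""Length-aware, density-preserving rewiring null models.

Each ORIGINAL edge is processed exactly once, in a configurable order
(random, shortest-to-longest, longest-to-shortest). A processed edge is
deleted and replaced by a pair that was absent in the original network and
has not yet been used as a replacement; the replacement is chosen at
random, or as the unused candidate of most similar length, or of most
dissimilar length. Vacated slots never re-enter the candidate pool, so
after t rewires the overlap with the original network is exactly
(m - t)/m and the edge count never changes.

Tracking the fit statistics of the progressively rewired network against
the original quantifies how sensitive each measure is to edge
displacement: distribution-based KS statistics move slowly (clustering
first) while edge identity degrades linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._pairs import pair_index
from .embedding import SpatialEmbedding
from .measures import FitResult, TopologyVectors, fit_result, topology_vectors
from .network import BinaryNetwork

__all__ = ["RewiringConfig", "RewiringTrajectory", "rewire_once",
           "rewire_partial", "rewiring_curves", "rewiring_ensemble"]


@dataclass(frozen=True)
class RewiringConfig:
    ordering: Literal["random", "ascending_length", "descending_length"] = "random"
    target_rule: Literal["random", "similar", "dissimilar"] = "random"
    n_runs: int = 30
    checkpoint_step: int | None = None  # default: every max(1, m // 100) rewires

    def __post_init__(self) -> None:
        if self.ordering not in ("random", "ascending_length", "descending_length"):
            raise ValueError(f"unknown ordering {self.ordering!r}")
        if self.target_rule not in ("random", "similar", "dissimilar"):
            raise ValueError(f"unknown target rule {self.target_rule!r}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.checkpoint_step is not None and self.checkpoint_step < 1:
            raise ValueError("checkpoint_step must be >= 1")


@dataclass
class RewiringTrajectory:
    """Per-checkpoint record of one rewiring pass."""

    proportions: np.ndarray                # strictly increasing, ends at 1
    fits: list[FitResult]                  # vs the ORIGINAL network
    mean_length_diff: float                # mean |len(edge) - len(target)|
    final: BinaryNetwork
    seed: int | None
    checkpoints: np.ndarray = field(default=None)  # rewire counts

    def frame(self) -> pd.DataFrame:
        rows = [f.to_dict() for f in self.fits]
        df = pd.DataFrame(rows)
        df.insert(0, "proportion_rewired", self.proportions)
        df.insert(0, "n_rewired", self.checkpoints)
        return df


class _LengthPool:
    """Candidate pool sorted by length with O(scan) nearest/extreme queries."""

    def __init__(self, pair_idx: np.ndarray, lengths: np.ndarray,
                 rng: np.random.Generator):
        order = np.argsort(lengths, kind="stable")
        self.idx = pair_idx[order]
        self.len = lengths[order]
        self.used = np.zeros(self.idx.size, dtype=bool)
        self.n_free = self.idx.size
        self.rng = rng
        self._free_lo = 0                 # lazy bounds for extreme queries
        self._free_hi = self.idx.size - 1

    def _nearest_free(self, pos: int, direction: int) -> int | None:
        while 0 <= pos < self.idx.size and self.used[pos]:
            pos += direction
        return pos if 0 <= pos < self.idx.size else None

    def take_random(self) -> int:
        free = np.flatnonzero(~self.used)
        pos = int(self.rng.choice(free))
        return self._take(pos)

    def take_similar(self, length: float) -> int:
        pos = int(np.searchsorted(self.len, length))
        left = self._nearest_free(pos - 1, -1)
        right = self._nearest_free(pos, +1)
        if left is None and right is None:
            raise RuntimeError("candidate pool exhausted")
        if left is None:
            return self._take(right)
        if right is None:
            return self._take(left)
        dl = abs(self.len[left] - length)
        dr = abs(self.len[right] - length)
        if dl == dr:
            return self._take(left if self.rng.random() < 0.5 else right)
        return self._take(left if dl < dr else right)

    def take_dissimilar(self, length: float) -> int:
        lo = self._nearest_free(self._free_lo, +1)
        hi = self._nearest_free(self._free_hi, -1)
        if lo is None:
            raise RuntimeError("candidate pool exhausted")
        self._free_lo, self._free_hi = lo, hi
        dl = abs(self.len[lo] - length)
        dh = abs(self.len[hi] - length)
        if dl == dh:
            return self._take(lo if self.rng.random() < 0.5 else hi)
        return self._take(lo if dl > dh else hi)

    def _take(self, pos: int) -> int:
        self.used[pos] = True
        self.n_free -= 1
        return pos


def _edge_order(edges: np.ndarray, lengths: np.ndarray, ordering: str,
                rng: np.random.Generator) -> np.ndarray:
    m = edges.shape[0]
    if ordering == "random":
        return rng.permutation(m)
    jitter = rng.random(m)  # randomises ties in the length sort
    key = np.lexsort((jitter, lengths))
    return key if ordering == "ascending_length" else key[::-1]


def rewire_once(network: BinaryNetwork, embedding: SpatialEmbedding,
                config: RewiringConfig, seed: int | None = None, *,
                max_rewires: int | None = None,
                measures: Literal["ks", "full", "none"] = "ks",
                target_vectors: TopologyVectors | None = None,
                ) -> RewiringTrajectory:
    """One full (or truncated) rewiring pass over a network.

    ``measures="none"`` skips all metric computation (used when only the
    final network matters, e.g. cohort generation).
    """
    m = network.m
    n = network.n
    if m == 0:
        raise ValueError("network has no edges to rewire")
    edges = network.edges()
    lengths = network.edge_lengths(embedding.D)
    present = network.condensed()
    q = present.size
    if m > q - m:
        raise ValueError("more edges than originally-absent pairs: "
                         "rewiring cannot complete")
    rng = np.random.default_rng(seed)

    absent_idx = np.flatnonzero(~present)
    pool = _LengthPool(absent_idx, embedding.d_condensed[absent_idx], rng)
    order = _edge_order(edges, lengths, config.ordering, rng)

    limit = m if max_rewires is None else min(max_rewires, m)
    step = config.checkpoint_step or max(1, m // 100)
    current = present.copy()
    tv = target_vectors
    if measures != "none" and tv is None:
        tv = topology_vectors(network, embedding)

    edge_pair_idx = pair_index(edges[:, 0], edges[:, 1], n)
    props, counts, fits = [], [], []
    diffs = []
    for t in range(limit):
        e = order[t]
        # delete the original edge, insert an unused originally-absent pair
        current[edge_pair_idx[e]] = False
        if config.target_rule == "random":
            pos = pool.take_random()
        elif config.target_rule == "similar":
            pos = pool.take_similar(lengths[e])
        else:
            pos = pool.take_dissimilar(lengths[e])
        current[pool.idx[pos]] = True
        diffs.append(abs(pool.len[pos] - lengths[e]))
        done = t + 1
        if measures != "none" and (done % step == 0 or done == limit):
            net_t = BinaryNetwork.from_pair_indices(n, np.flatnonzero(current))
            fits.append(fit_result(net_t, network, embedding,
                                   include_alt=(measures == "full"),
                                   target_vectors=tv))
            props.append(done / m)
            counts.append(done)

    final = BinaryNetwork.from_pair_indices(n, np.flatnonzero(current))
    return RewiringTrajectory(
        proportions=np.asarray(props), fits=fits,
        mean_length_diff=float(np.mean(diffs)) if diffs else float("nan"),
        final=final, seed=seed, checkpoints=np.asarray(counts, dtype=int))


def rewire_partial(network: BinaryNetwork, embedding: SpatialEmbedding,
                   n_rewires: int, seed: int | None = None,
                   config: RewiringConfig | None = None) -> BinaryNetwork:
    """Convenience: relocate ``n_rewires`` edges and return the network."""
    cfg = config or RewiringConfig(ordering="random", target_rule="similar")
    if n_rewires == 0:
        return BinaryNetwork(network.A.copy())
    traj = rewire_once(network, embedding, cfg, seed,
                       max_rewires=n_rewires, measures="none")
    return traj.final


def rewiring_ensemble(network: BinaryNetwork, embedding: SpatialEmbedding,
                      config: RewiringConfig, seed: int | None = None,
                      ) -> list[RewiringTrajectory]:
    """Run the configured rewiring model ``config.n_runs`` times."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(config.n_runs)
    tv = topology_vectors(network, embedding)
    return [rewire_once(network, embedding, config,
                        seed=int(c.generate_state(1)[0] % (2 ** 31)),
                        target_vectors=tv)
            for c in children]


def rewiring_curves(trajectories: list[RewiringTrajectory],
                    measure: str = "maxKS") -> pd.DataFrame:
    """Pointwise mean (and SD) of one measure across rewiring runs."""
    if not trajectories:
        raise ValueError("no trajectories")
    grid = trajectories[0].proportions
    vals = []
    for tr in trajectories:
        if tr.proportions.shape != grid.shape or \
                not np.allclose(tr.proportions, grid):
            raise ValueError("trajectories have mismatched checkpoint grids")
        vals.append([getattr(f, measure) if hasattr(f, measure)
                     else f.alt[measure] for f in tr.fits])
    arr = np.asarray(vals, dtype=float)
    return pd.DataFrame({
        "proportion_rewired": grid,
        "mean": arr.mean(axis=0),
        "sd": arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(grid.size),
        "n_runs": arr.shape[0],
    })
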