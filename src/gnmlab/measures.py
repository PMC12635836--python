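"""Nodal statistics and network-pair similarity measures.

The fit statistic used throughout is max(KS): the largest of four
two-sample Kolmogorov–Smirnov statistics comparing the degree, clustering,
betweenness and edge-length distributions of two networks on the same
embedding. Because KS compares distributions, max(KS) is blind to WHERE
properties sit in space — the motivation for the complementary measures
here: edge recovery R, Jaccard overlap, false-discovery rate of formed
edges, nodal degree correlation, and a set of alternative whole-network
discrepancy summaries (TND, TF_diff, max r_d, max RMSE).

Nodal measures are computed through igraph's C implementations
(Brandes betweenness with raw unordered-pair dependency counts,
Watts–Strogatz local clustering with the degree-<2 convention of zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from scipy import stats

from .embedding import SpatialEmbedding
from .network import BinaryNetwork

__all__ = [
    "TopologyVectors", "FitResult", "topology_vectors", "ks_stat", "max_ks",
    "recovery_overlap", "degree_correlation", "alt_measures",
    "distance_binned_recovery", "DEFAULT_BIN_EDGES", "fit_result",
]

#: short / mid / long-range length bins, mm, half-open [lo, hi)
DEFAULT_BIN_EDGES = (0.0, 30.0, 90.0, np.inf)


@dataclass
class TopologyVectors:
    degree: np.ndarray          # per-node integer
    clustering: np.ndarray      # per-node Watts–Strogatz local clustering
    betweenness: np.ndarray     # per-node raw Brandes dependency counts
    edge_lengths: np.ndarray    # per-edge, mm
    node_mean_length: np.ndarray  # per-node mean incident edge length, mm
    isolated: np.ndarray = field(default=None)  # nodes with degree 0 (flag)


def _igraph_of(net: BinaryNetwork) -> ig.Graph:
    return ig.Graph(net.n, [tuple(e) for e in net.edges()])


def topology_vectors(net: BinaryNetwork,
                     embedding: SpatialEmbedding) -> TopologyVectors:
    """The four nodal/edge statistic vectors of one network."""
    if net.n != embedding.n:
        raise ValueError("network and embedding disagree on node count")
    g = _igraph_of(net)
    k = np.asarray(g.degree(), dtype=np.int64)
    c = np.asarray(g.transitivity_local_undirected(mode="zero"), dtype=float)
    b = np.asarray(g.betweenness(), dtype=float)
    e = net.edge_lengths(embedding.D)
    # mean incident edge length; isolated nodes get 0, flagged
    tot = (net.A * embedding.D).sum(axis=1)
    with np.errstate(invalid="ignore"):
        nml = np.divide(tot, k, out=np.zeros(net.n), where=k > 0)
    return TopologyVectors(degree=k, clustering=c, betweenness=b,
                           edge_lengths=e, node_mean_length=nml,
                           isolated=(k == 0))


def ks_stat(x, y) -> float:
    """Two-sample Kolmogorov–Smirnov statistic.

    Supremum of the absolute difference of the two empirical CDFs
    (right-continuous step functions), attained at a pooled sample point.
    """
    x = np.sort(np.asarray(x, dtype=float).ravel())
    y = np.sort(np.asarray(y, dtype=float).ravel())
    if x.size == 0 or y.size == 0:
        raise ValueError("KS statistic requires non-empty samples")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    return float(np.abs(cdf_x - cdf_y).max())


def max_ks(net_a: BinaryNetwork, net_b: BinaryNetwork,
           embedding: SpatialEmbedding,
           vectors_a: TopologyVectors | None = None,
           vectors_b: TopologyVectors | None = None) -> dict[str, float]:
    """Component KS statistics and their maximum for a network pair.

    Returns a dict with keys ``KS_k``, ``KS_c``, ``KS_b``, ``KS_e``,
    ``maxKS``. Precomputed :func:`topology_vectors` may be passed to avoid
    rescoring a fixed target.
    """
    ta = vectors_a or topology_vectors(net_a, embedding)
    tb = vectors_b or topology_vectors(net_b, embedding)
    if net_a.m == 0 or net_b.m == 0:
        raise ValueError("KS on edge lengths undefined for edgeless networks")
    out = {
        "KS_k": ks_stat(ta.degree, tb.degree),
        "KS_c": ks_stat(ta.clustering, tb.clustering),
        "KS_b": ks_stat(ta.betweenness, tb.betweenness),
        "KS_e": ks_stat(ta.edge_lengths, tb.edge_lengths),
    }
    out["maxKS"] = max(out.values())
    return out


def recovery_overlap(model_net: BinaryNetwork,
                     target_net: BinaryNetwork) -> dict[str, float]:
    """Edge recovery R, Jaccard overlap, and formed-edge FDR.

    R = |E_model ∩ E_target| / |E_target| — the fraction of target edges
    the model reproduces; fdr = fraction of model edges absent from the
    target.
    """
    if target_net.m == 0:
        raise ValueError("target network has no edges")
    if model_net.n != target_net.n:
        raise ValueError("node sets differ")
    if model_net.m != target_net.m:
        warnings.warn("networks differ in edge count; R and fdr are not "
                      "complementary", stacklevel=2)
    inter = int(np.logical_and(model_net.A, target_net.A).sum()) // 2
    union = int(np.logical_or(model_net.A, target_net.A).sum()) // 2
    r = inter / target_net.m
    jac = inter / union if union else 1.0
    fdr = 1.0 - inter / model_net.m if model_net.m else 0.0
    return {"R": r, "jaccard": jac, "fdr": fdr, "n_common": inter}


def degree_correlation(net_a: BinaryNetwork, net_b: BinaryNetwork,
                       method: str = "spearman") -> float:
    """Rank (Spearman, average-rank ties) or Pearson correlation of degrees."""
    ka, kb = net_a.degree, net_b.degree
    if ka.size != kb.size:
        raise ValueError("node sets differ")
    if np.ptp(ka) == 0 or np.ptp(kb) == 0:
        warnings.warn("zero-variance degree vector: correlation undefined",
                      stacklevel=2)
        return float("nan")
    if method == "spearman":
        return float(stats.spearmanr(ka, kb).statistic)
    if method == "pearson":
        return float(stats.pearsonr(ka, kb).statistic)
    raise ValueError(f"unknown method {method!r}")


# --- alternative whole-network measures -----------------------------------

def _global_summaries(net: BinaryNetwork, seed: int = 0) -> np.ndarray:
    """Global topology summary vector: transitivity, efficiency,
    modularity Q (Louvain, seeded), degree assortativity."""
    import networkx as nx

    g = _igraph_of(net)
    trans = g.transitivity_undirected(mode="zero")
    # global efficiency: mean inverse shortest-path length over ordered pairs
    sp = np.asarray(g.distances())
    n = net.n
    with np.errstate(divide="ignore"):
        inv = 1.0 / sp
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    eff = inv.sum() / (n * (n - 1)) if n > 1 else 0.0
    G = nx.from_numpy_array(net.A)
    if net.m:
        comm = nx.community.louvain_communities(G, seed=seed)
        q = nx.community.modularity(G, comm)
    else:
        q = 0.0
    try:
        assort = nx.degree_assortativity_coefficient(G) if net.m else 0.0
        if not np.isfinite(assort):
            assort = 0.0
    except Exception:
        assort = 0.0
    return np.array([trans, eff, q, assort], dtype=float)


def _safe_corrcoef(vectors: np.ndarray) -> np.ndarray:
    """Correlation matrix with zero-variance rows flagged as 0 correlation."""
    v = np.asarray(vectors, dtype=float)
    sd = v.std(axis=1)
    bad = sd == 0
    if bad.any():
        warnings.warn("zero-variance nodal vector in correlation matrix; "
                      "its correlations are set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(v)
    c[np.isnan(c)] = 0.0
    if bad.any():
        c[bad, :] = 0.0
        c[:, bad] = 0.0
        np.fill_diagonal(c, 1.0)
    return c


def _harmonic_closeness(net: BinaryNetwork) -> np.ndarray:
    g = _igraph_of(net)
    return np.asarray(g.harmonic_centrality(normalized=True), dtype=float)


def alt_measures(net_a: BinaryNetwork, net_b: BinaryNetwork,
                 embedding: SpatialEmbedding, seed: int = 0) -> dict[str, float]:
    """Alternative discrepancy measures between two networks.

    TND
        Euclidean distance between z-scored global-summary vectors
        (transitivity, global efficiency, Louvain modularity Q, degree
        assortativity); z-scoring pools both networks' values.
    TF_diff
        Frobenius norm of the difference of the two 4x4 correlation
        matrices of the nodal vectors (degree, clustering, betweenness,
        mean incident edge length).
    max_rd
        Maximum Pearson distance (1 - r) across the four matched nodal
        vectors.
    max_RMSE
        Maximum root-mean-square difference across matched nodal vectors
        (degree, clustering, harmonic closeness, mean incident length),
        each min-max rescaled jointly across the two networks.
    """
    ta = topology_vectors(net_a, embedding)
    tb = topology_vectors(net_b, embedding)

    ga = _global_summaries(net_a, seed=seed)
    gb = _global_summaries(net_b, seed=seed)
    both = np.vstack([ga, gb])
    mu, sd = both.mean(axis=0), both.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    tnd = float(np.linalg.norm((ga - mu) / sd - (gb - mu) / sd))

    feats_a = np.vstack([ta.degree, ta.clustering, ta.betweenness,
                         ta.node_mean_length])
    feats_b = np.vstack([tb.degree, tb.clustering, tb.betweenness,
                         tb.node_mean_length])
    tf_diff = float(np.linalg.norm(_safe_corrcoef(feats_a)
                                   - _safe_corrcoef(feats_b)))

    rds = []
    for va, vb in zip(feats_a, feats_b):
        if va.std() == 0 or vb.std() == 0:
            warnings.warn("zero-variance vector in max_rd; component skipped",
                          stacklevel=2)
            continue
        rds.append(1.0 - float(stats.pearsonr(va, vb).statistic))
    max_rd = float(max(rds)) if rds else float("nan")

    rmse_vecs_a = [ta.degree.astype(float), ta.clustering,
                   _harmonic_closeness(net_a), ta.node_mean_length]
    rmse_vecs_b = [tb.degree.astype(float), tb.clustering,
                   _harmonic_closeness(net_b), tb.node_mean_length]
    rmses = []
    for va, vb in zip(rmse_vecs_a, rmse_vecs_b):
        lo = min(va.min(), vb.min())
        hi = max(va.max(), vb.max())
        if hi == lo:
            rmses.append(0.0)
            continue
        sa = (va - lo) / (hi - lo)
        sb = (vb - lo) / (hi - lo)
        rmses.append(float(np.sqrt(np.mean((sa - sb) ** 2))))
    return {"TND": tnd, "TF_diff": tf_diff, "max_rd": max_rd,
            "max_RMSE": float(max(rmses))}


@dataclass
class FitResult:
    """All similarity measures for one (model, target) network pair."""

    KS_k: float
    KS_c: float
    KS_b: float
    KS_e: float
    maxKS: float
    R: float
    jaccard: float
    fdr: float
    rho_degree: float
    alt: dict | None = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("KS_k", "KS_c", "KS_b", "KS_e", "maxKS", "R", "jaccard",
              "fdr", "rho_degree")}
        if self.alt:
            d.update(self.alt)
        return d


def fit_result(model_net: BinaryNetwork, target_net: BinaryNetwork,
               embedding: SpatialEmbedding, *, include_alt: bool = False,
               target_vectors: TopologyVectors | None = None,
               seed: int = 0) -> FitResult:
    """Bundle max(KS), recovery and degree correlation for one pair."""
    ks = max_ks(model_net, target_net, embedding, vectors_b=target_vectors)
    ro = recovery_overlap(model_net, target_net)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = degree_correlation(model_net, target_net)
    alt = alt_measures(model_net, target_net, embedding, seed=seed) \
        if include_alt else None
    return FitResult(KS_k=ks["KS_k"], KS_c=ks["KS_c"], KS_b=ks["KS_b"],
                     KS_e=ks["KS_e"], maxKS=ks["maxKS"], R=ro["R"],
                     jaccard=ro["jaccard"], fdr=ro["fdr"], rho_degree=rho,
                     alt=alt)


def distance_binned_recovery(model_net: BinaryNetwork,
                             target_net: BinaryNetwork,
                             embedding: SpatialEmbedding,
                             bin_edges=DEFAULT_BIN_EDGES):
    """Edge recovery restricted to target edges in half-open length bins.

    Returns a list of dicts with keys ``lo``, ``hi``, ``n_target``,
    ``recovery`` and ``valid``; bins with no target edges are flagged
    invalid rather than reported as zero.
    """
    edges = target_net.edges()
    if edges.size == 0:
        raise ValueError("target network has no edges")
    lengths = target_net.edge_lengths(embedding.D)
    if lengths.max() >= bin_edges[-1]:
        raise ValueError("bin edges do not cover all target edge lengths")
    inter = np.logical_and(model_net.A, target_net.A)
    hit = inter[edges[:, 0], edges[:, 1]]
    out = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        mask = (lengths >= lo) & (lengths < hi)
        nt = int(mask.sum())
        rec = float(hit[mask].mean()) if nt else float("nan")
        out.append({"lo": float(lo), "hi": float(hi), "n_target": nt,
                    "recovery": rec, "valid": nt > 0})
    return out
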