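"""Distance-resolved diagnostics of model topography.

These analyses probe WHERE a model places its edges rather than how its
topology is distributed: how much of a network's degree sequence is
carried by connections below/above a length threshold, how the mean
growth probability of a pair relates to its length, and how precise the
model's high-probability picks are within narrow distance windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._pairs import condense, triu_pairs
from .embedding import SpatialEmbedding
from .measures import DEFAULT_BIN_EDGES
from .network import BinaryNetwork

__all__ = ["ThresholdProfile", "WindowCurve", "distance_threshold_degree",
           "probability_vs_distance", "sliding_window_precision",
           "formed_edge_fdr"]


@dataclass
class ThresholdProfile:
    """Correlation of length-thresholded degree with the full degree."""

    thresholds: np.ndarray
    r: np.ndarray               # Pearson r per threshold (NaN where invalid)
    valid: np.ndarray           # False where the thresholded degree is constant
    mode: str

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold_mm": self.thresholds, "r": self.r,
                             "valid": self.valid, "mode": self.mode})


def distance_threshold_degree(network: BinaryNetwork,
                              embedding: SpatialEmbedding,
                              thresholds, mode: str = "below",
                              ) -> ThresholdProfile:
    """Degree computed from edges on one side of a length threshold.

    ``mode="below"`` keeps edges with length < threshold (how well short
    connections alone explain the degree sequence); ``mode="above"``
    keeps length >= threshold. The two modes decompose the full degree
    exactly: k_below(t) + k_above(t) = k for every node and threshold.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold grid")
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    if mode not in ("below", "above"):
        raise ValueError(f"unknown mode {mode!r}")
    full_k = network.degree.astype(float)
    if np.ptp(full_k) == 0:
        raise ValueError("full degree sequence is constant; "
                         "correlation undefined")
    rs = np.full(thresholds.size, np.nan)
    valid = np.zeros(thresholds.size, dtype=bool)
    for i, t in enumerate(thresholds):
        if mode == "below":
            keep = network.A * (embedding.D < t)
        else:
            keep = network.A * (embedding.D >= t)
        k = keep.sum(axis=1).astype(float)
        if np.ptp(k) == 0:
            continue
        rs[i] = float(stats.pearsonr(k, full_k).statistic)
        valid[i] = True
    return ThresholdProfile(thresholds=thresholds, r=rs, valid=valid,
                            mode=mode)


def probability_vs_distance(mean_P: np.ndarray, target_net: BinaryNetwork,
                            embedding: SpatialEmbedding,
                            ) -> tuple[pd.DataFrame, float]:
    """Tidy per-pair table of (distance, mean probability, target edge).

    Returns the table over all n(n-1)/2 pairs and the Spearman rank
    correlation between pair distance and mean growth probability.
    """
    mean_P = np.asarray(mean_P, dtype=float)
    n = embedding.n
    if mean_P.shape != (n, n):
        raise ValueError("mean_P shape does not match the embedding")
    i, j = triu_pairs(n)
    d = embedding.d_condensed
    p = condense(mean_P)
    is_edge = target_net.condensed()
    df = pd.DataFrame({"i": i, "j": j, "distance_mm": d, "mean_p": p,
                       "is_target_edge": is_edge})
    rho = float(stats.spearmanr(d, p).statistic)
    return df, rho


@dataclass
class WindowCurve:
    """Sliding-window precision of high-probability pairs."""

    centers: np.ndarray
    half_width: float
    top_fracs: tuple
    precision: np.ndarray        # (n_centers, n_fracs)
    null: np.ndarray             # base rate of target edges per window
    n_pairs: np.ndarray
    valid: np.ndarray            # False where the window is under-occupied

    def frame(self) -> pd.DataFrame:
        rows = []
        for ci, c in enumerate(self.centers):
            for fi, f in enumerate(self.top_fracs):
                rows.append({"center_mm": c, "top_frac": f,
                             "precision": self.precision[ci, fi],
                             "null": self.null[ci],
                             "n_pairs": int(self.n_pairs[ci]),
                             "valid": bool(self.valid[ci])})
        return pd.DataFrame(rows)


def sliding_window_precision(mean_P: np.ndarray, target_net: BinaryNetwork,
                             embedding: SpatialEmbedding, *,
                             half_width: float = 5.0,
                             top_fracs=(0.05, 0.10, 0.25),
                             center_step: float = 1.0,
                             min_pairs: int = 10,
                             seed: int | None = None) -> WindowCurve:
    """Precision of the top-probability pairs within distance windows.

    For each window centre c, all node pairs with distance within
    c ± half_width are collected; the top ceil(f * count) pairs by mean
    growth probability (ties randomised) are selected, and precision is
    the fraction of selected pairs that are target edges. The null is the
    window's base rate of target edges — the precision expected if every
    pair at that distance were equally probable.
    """
    mean_P = np.asarray(mean_P, dtype=float)
    n = embedding.n
    if mean_P.shape != (n, n):
        raise ValueError("mean_P shape does not match the embedding")
    d = embedding.d_condensed
    p = condense(mean_P)
    is_edge = target_net.condensed()
    rng = np.random.default_rng(seed)
    tie_break = rng.random(p.size)

    centers = np.arange(np.ceil(d.min()), np.floor(d.max()) + 1e-9,
                        center_step)
    prec = np.full((centers.size, len(top_fracs)), np.nan)
    null = np.full(centers.size, np.nan)
    npairs = np.zeros(centers.size, dtype=int)
    valid = np.zeros(centers.size, dtype=bool)
    order_key = np.lexsort((tie_break, -p))     # descending p, random ties
    rank = np.empty(p.size, dtype=np.int64)
    rank[order_key] = np.arange(p.size)
    for ci, c in enumerate(centers):
        win = np.abs(d - c) <= half_width
        cnt = int(win.sum())
        npairs[ci] = cnt
        if cnt == 0:
            continue
        null[ci] = float(is_edge[win].mean())
        valid[ci] = cnt >= min_pairs
        win_idx = np.flatnonzero(win)
        win_rank = rank[win_idx]
        by_rank = win_idx[np.argsort(win_rank)]
        for fi, f in enumerate(top_fracs):
            k = int(np.ceil(f * cnt))
            sel = by_rank[:k]
            prec[ci, fi] = float(is_edge[sel].mean())
    return WindowCurve(centers=centers, half_width=half_width,
                       top_fracs=tuple(top_fracs), precision=prec,
                       null=null, n_pairs=npairs, valid=valid)


def formed_edge_fdr(model_net: BinaryNetwork, target_net: BinaryNetwork,
                    embedding: SpatialEmbedding,
                    bin_edges=DEFAULT_BIN_EDGES) -> list[dict]:
    """Per-length-bin false-discovery rate of the model's formed edges.

    For each half-open bin [lo, hi), the fraction of MODEL edges in that
    length range that are absent from the target. Bins with no model
    edges are flagged invalid.
    """
    edges = model_net.edges()
    if edges.size == 0:
        raise ValueError("model network has no edges")
    lengths = model_net.edge_lengths(embedding.D)
    in_target = target_net.A[edges[:, 0], edges[:, 1]].astype(bool)
    out = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        mask = (lengths >= lo) & (lengths < hi)
        nm = int(mask.sum())
        fdr = float(1.0 - in_target[mask].mean()) if nm else float("nan")
        out.append({"lo": float(lo), "hi": float(hi), "n_model": nm,
                    "fdr": fdr, "valid": nm > 0})
    return out
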