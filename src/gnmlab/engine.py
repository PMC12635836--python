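"""Generative network model engine.

A generative network model (GNM) grows a binary network edge by edge.
At each step every absent node pair (i, j) receives a wiring weight

    additive:        w_ij = e^(-eta * D_ij) / max(e^(-eta * D))
                            + alpha * F_ij^gamma / max(F^gamma)
    multiplicative:  w_ij = [e^(-eta * D_ij) / max(e^(-eta * D))]
                            * [F_ij^gamma / max(F^gamma)]

where D is the wiring-cost (distance) matrix, F a pairwise feature in
[0, 1], and each ``max`` runs over the pairs not yet connected. With a
power-law decay the distance kernel is D^(-eta) instead of e^(-eta D).
Weights are converted to probabilities by normalising over absent pairs,

    P_ij = w_ij (1 - A_ij) / sum_{u<v} w_uv (1 - A_uv),

and exactly one edge is sampled per step. The feature source may be
absent (pure spatial model), a static similarity matrix, or the matching
index — the normalised neighbourhood overlap of the growing network
itself, recomputed after every added edge.

Numerical notes
---------------
Both terms are evaluated in log space relative to their extremum over the
absent pairs, which is algebraically identical to the ratio form but
immune to underflow (F^gamma with gamma up to 200 underflows in double
precision long before it stops mattering). Features are clamped below at
``F_EPS`` so that negative exponents stay defined. When every raw feature
value over the absent pairs sits at or below the clamp floor — the
matching model's empty-network start — the feature carries no signal and
its term is dropped (additive) or set to one (multiplicative), so the
first step of a matching model reproduces the spatial model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Union

import numpy as np

from ._pairs import condense, n_pairs, square, triu_pairs
from .embedding import SpatialEmbedding
from .network import BinaryNetwork

__all__ = [
    "GNMParams", "ModelSpec", "GrowthTrace", "wiring_weights",
    "connection_probabilities", "grow_network", "matching_index",
    "mean_connection_probability", "F_EPS",
]

#: clamp floor applied to features before exponentiation
F_EPS = 1e-6


@dataclass(frozen=True)
class GNMParams:
    """Wiring-rule parameters.

    eta
        Distance-penalty strength (>= 0). Exponential decay is typically
        searched on [0, 2], power-law on [0, 10].
    gamma
        Feature exponent; positive values reward similar pairs.
    alpha
        Weight of the feature term, additive form only. ``None`` for the
        spatial model and for multiplicative rules (which have no alpha).
    form
        ``"additive"`` or ``"multiplicative"``.
    decay
        ``"exponential"`` or ``"powerlaw"`` distance kernel.
    """

    eta: float = 0.0
    gamma: float = 0.0
    alpha: Optional[float] = None
    form: Literal["additive", "multiplicative"] = "additive"
    decay: Literal["exponential", "powerlaw"] = "exponential"

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.form not in ("additive", "multiplicative"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.decay not in ("exponential", "powerlaw"):
            raise ValueError(f"unknown decay {self.decay!r}")
        if self.form == "multiplicative" and self.alpha is not None:
            raise ValueError("multiplicative rule has no alpha; leave it unset")
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be non-negative")


FeatureSource = Union[None, str, np.ndarray]


@dataclass
class ModelSpec:
    """One generative model: parameters plus a feature source.

    feature_source
        ``None`` or ``"spatial"`` — pure wiring-cost model (feature term
        absent); ``"matching"`` — dynamic matching-index homophily;
        an ``(n, n)`` similarity matrix in [0, 1] — static feature model.
    """

    params: GNMParams = field(default_factory=GNMParams)
    feature_source: FeatureSource = None
    label: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.feature_source, str):
            if self.feature_source == "spatial":
                self.feature_source = None
            elif self.feature_source != "matching":
                raise ValueError(
                    f"unknown feature source {self.feature_source!r}")
        elif self.feature_source is not None:
            F = np.asarray(self.feature_source, dtype=float)
            if F.ndim != 2 or F.shape[0] != F.shape[1]:
                raise ValueError("static feature matrix must be square")
            if not np.allclose(F, F.T):
                raise ValueError("static feature matrix must be symmetric")
            off = condense(F)
            if off.min() < 0 or off.max() > 1:
                raise ValueError("feature values must lie in [0, 1]")
            self.feature_source = F
        if not self.label:
            self.label = self.kind

    @property
    def kind(self) -> str:
        if self.feature_source is None:
            return "spatial"
        if isinstance(self.feature_source, str):
            return "matching"
        return "static"

    @property
    def is_spatial(self) -> bool:
        return self.feature_source is None

    @property
    def is_dynamic(self) -> bool:
        return isinstance(self.feature_source, str)


@dataclass
class GrowthTrace:
    """Bookkeeping of one growth run.

    ``mean_P[i, j]`` is the mean of the per-step connection probability of
    pair (i, j) over the steps at which the pair was still absent: steps
    1..t for a pair added at step t, all m steps for a never-added pair.
    """

    edge_order: np.ndarray            # (m, 2) pairs in order of addition
    mean_P: np.ndarray                # (n, n) symmetric
    step_count_P: np.ndarray          # (n, n) integer step counts
    completed: bool = False
    tracked: bool = True                        # False when probabilities were not accumulated
    prob_sum_max_abs_err: float | None = None   # debug-mode conservation check
    step_log: np.ndarray | None = None          # optional (m, n_pairs) full log


def _distance_term(d: np.ndarray, absent: np.ndarray, params: GNMParams,
                   logd: np.ndarray | None = None) -> np.ndarray:
    """Normalised distance kernel over all pairs (valid on absent ones)."""
    if params.eta == 0:
        return np.ones_like(d)
    if params.decay == "exponential":
        ref = d[absent].min()
        return np.exp(-params.eta * (d - ref))
    ref = logd[absent].min()
    return np.exp(-params.eta * (logd - ref))


def _feature_term(f_raw: np.ndarray, absent: np.ndarray,
                  gamma: float) -> np.ndarray | None:
    """Normalised feature kernel, or None when the feature has no signal.

    Returns the term F^gamma / ext(F^gamma) over absent pairs, evaluated
    in log space. ``None`` signals that every raw feature value over the
    absent pairs is at or below the clamp floor, i.e. the feature is
    uninformative and the term should be dropped/unity.
    """
    fa = f_raw[absent]
    if fa.max() <= F_EPS:
        return None
    if gamma == 0:
        return np.ones_like(f_raw)
    logf = np.log(np.maximum(f_raw, F_EPS))
    ext = logf[absent].max() if gamma > 0 else logf[absent].min()
    return np.exp(gamma * (logf - ext))


def _combine(td: np.ndarray, tf: np.ndarray | None,
             params: GNMParams) -> np.ndarray:
    if params.form == "additive":
        if tf is None:
            return td
        alpha = params.alpha
        if alpha is None:
            raise ValueError("additive feature model requires alpha")
        return td + alpha * tf
    return td if tf is None else td * tf


def wiring_weights(D: np.ndarray, F: np.ndarray | None, A: np.ndarray,
                   params: GNMParams) -> tuple[np.ndarray, np.ndarray]:
    """Wiring weights over the currently absent pairs.

    Parameters
    ----------
    D : (n, n) distance matrix
    F : (n, n) feature matrix in [0, 1], or None for the spatial model
    A : (n, n) current binary adjacency
    params : GNMParams

    Returns
    -------
    weights : 1-D array over absent pairs
    pairs : (q, 2) node-index pairs the weights refer to, i < j
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    d = condense(D)
    if params.decay == "powerlaw" and np.any(d <= 0):
        raise ValueError("power-law decay requires strictly positive distances")
    absent = ~condense(np.asarray(A)).astype(bool)
    if not absent.any():
        raise ValueError("no absent pairs: network is complete")
    logd = np.log(d) if params.decay == "powerlaw" else None
    td = _distance_term(d, absent, params, logd)
    tf = None
    if F is not None:
        tf = _feature_term(condense(np.asarray(F, dtype=float)), absent,
                           params.gamma)
    w = _combine(td, tf, params)
    i, j = triu_pairs(n)
    keep = absent
    return w[keep], np.column_stack([i[keep], j[keep]])


def connection_probabilities(weights: np.ndarray) -> np.ndarray:
    """Normalise wiring weights over absent pairs to probabilities.

    The weights must already be restricted to absent pairs (present pairs
    have probability zero by construction and are not represented).
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("no absent pairs")
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("weights must be finite and non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("all weights are zero; probabilities undefined")
    return w / total


def matching_index(A: np.ndarray | BinaryNetwork) -> np.ndarray:
    """Matching index: normalised overlap of two nodes' neighbourhoods.

    m_ij = |N(i) ∩ N(j)| / |N(i) ∪ N(j)| with both neighbourhoods taken
    excluding i and j themselves; 0 when the union is empty. Diagonal 0.
    """
    if isinstance(A, BinaryNetwork):
        A = A.A
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    cn = A @ A                       # common neighbours (exclude i, j naturally)
    k = A.sum(axis=1)
    union = k[:, None] + k[None, :] - 2 * A - cn
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(union > 0, cn / np.where(union > 0, union, 1), 0.0)
    np.fill_diagonal(m, 0.0)
    return m


def _matching_rows(A: np.ndarray, k: np.ndarray, nodes) -> np.ndarray:
    """Matching-index rows for the given nodes (vectorised partial update)."""
    cn = A[nodes] @ A                    # (len(nodes), n)
    union = k[nodes][:, None] + k[None, :] - 2 * A[nodes] - cn
    with np.errstate(divide="ignore", invalid="ignore"):
        rows = np.where(union > 0, cn / np.where(union > 0, union, 1), 0.0)
    for r, u in enumerate(np.atleast_1d(nodes)):
        rows[r, u] = 0.0
    return rows


def _static_eligible(spec: ModelSpec) -> bool:
    """True when relative weights over absent pairs are step-invariant.

    The max-normalisers of both terms rescale every absent pair equally in
    the multiplicative form, and the spatial model has a single term, so
    the per-step probability vector is a fixed weight vector renormalised
    over the shrinking absent set. Sequential sampling then coincides with
    weighted sampling without replacement. Additive static models break
    the invariance (the two normalisers drift at different rates).
    """
    if spec.is_spatial:
        return True
    return (spec.kind == "static") and spec.params.form == "multiplicative"


def _static_raw_weights(emb: SpatialEmbedding, spec: ModelSpec) -> np.ndarray:
    d = emb.d_condensed
    p = spec.params
    if p.decay == "powerlaw":
        if np.any(d <= 0):
            raise ValueError("power-law decay requires positive distances")
        td = np.exp(-p.eta * (np.log(d) - np.log(d).min()))
    else:
        td = np.exp(-p.eta * (d - d.min()))
    if spec.is_spatial:
        return td
    f_raw = condense(np.asarray(spec.feature_source, dtype=float))
    tf = _feature_term(f_raw, np.ones_like(f_raw, dtype=bool), p.gamma)
    return td if tf is None else td * tf


def grow_network(embedding: SpatialEmbedding, spec: ModelSpec, m_target: int,
                 seed: int | None = None, *, trace: bool = True,
                 debug: bool = False, keep_step_log: bool = False,
                 method: Literal["auto", "stepwise", "static"] = "auto",
                 ) -> tuple[BinaryNetwork, GrowthTrace | None]:
    """Grow a network of ``m_target`` edges from an empty adjacency matrix.

    Parameters
    ----------
    trace
        Record edge order and mean per-step connection probabilities.
        Disabling the trace permits the fast static-weights path for
        models whose relative weights do not change between steps.
    debug
        Assert per-step probability conservation (sum over absent pairs
        equals 1 within 1e-12) and record the worst deviation.
    keep_step_log
        Additionally retain the full (m, n_pairs) per-step probability
        array — test-oracle use only, quadratic memory.
    method
        ``"stepwise"`` forces the reference sequential loop;
        ``"static"`` forces the sampling-without-replacement shortcut
        (only valid for step-invariant models); ``"auto"`` picks the
        shortcut when it is valid and no trace was requested.
    """
    n = embedding.n
    q = n_pairs(n)
    if m_target > q:
        raise ValueError(f"m_target={m_target} exceeds capacity {q}")
    if m_target < 0:
        raise ValueError("m_target must be non-negative")

    want_static = method == "static" or (
        method == "auto" and not trace and not debug and not keep_step_log
        and _static_eligible(spec))
    if method == "static" and not _static_eligible(spec):
        raise ValueError("static method invalid: weights change between steps")

    if want_static:
        net = _grow_static(embedding, spec, m_target, seed)
        return net, None
    return _grow_stepwise(embedding, spec, m_target, seed, trace=trace,
                          debug=debug, keep_step_log=keep_step_log)


def _grow_static(emb: SpatialEmbedding, spec: ModelSpec, m_target: int,
                 seed) -> BinaryNetwork:
    # Exponential race: pair with the k-th smallest Exp(1)/w key is the
    # k-th edge drawn by successive sampling proportional to w.
    rng = np.random.default_rng(seed)
    w = _static_raw_weights(emb, spec)
    keys = rng.exponential(size=w.size) / w
    chosen = np.argpartition(keys, m_target - 1)[:m_target] if m_target else \
        np.empty(0, dtype=np.int64)
    return BinaryNetwork.from_pair_indices(emb.n, chosen)


def _grow_stepwise(emb: SpatialEmbedding, spec: ModelSpec, m_target: int,
                   seed, *, trace: bool, debug: bool,
                   keep_step_log: bool) -> tuple[BinaryNetwork, GrowthTrace]:
    n = emb.n
    q = n_pairs(n)
    p_ = spec.params
    rng = np.random.default_rng(seed)
    d = emb.d_condensed
    if p_.decay == "powerlaw" and np.any(d <= 0):
        raise ValueError("power-law decay requires strictly positive distances")
    logd = np.log(d) if p_.decay == "powerlaw" else None
    iu_i, iu_j = triu_pairs(n)

    static_f = None
    dynamic_matching = spec.is_dynamic
    if spec.kind == "static":
        static_f = condense(np.asarray(spec.feature_source, dtype=float))
    A = np.zeros((n, n), dtype=np.int8)
    k_deg = np.zeros(n, dtype=np.int64)
    Fm = np.zeros((n, n)) if dynamic_matching else None

    absent = np.ones(q, dtype=bool)
    order = np.empty((m_target, 2), dtype=np.int64)
    sum_P = np.zeros(q)
    cnt_P = np.zeros(q, dtype=np.int64)
    log_rows = np.zeros((m_target, q)) if keep_step_log else None
    max_err = 0.0

    for t in range(m_target):
        td = _distance_term(d, absent, p_, logd)
        if spec.is_spatial:
            f_raw = None
        elif dynamic_matching:
            f_raw = condense(Fm)
        else:
            f_raw = static_f
        tf = None if f_raw is None else _feature_term(f_raw, absent, p_.gamma)
        w = _combine(td, tf, p_)
        w = np.where(absent, w, 0.0)
        total = w.sum()
        if total <= 0 or not np.isfinite(total):
            raise ValueError("degenerate weights: cannot form probabilities")
        p = w / total
        if debug:
            err = abs(p[absent].sum() - 1.0)
            if err > 1e-12:
                raise AssertionError(
                    f"probability conservation violated at step {t}: {err:.3e}")
            max_err = max(max_err, err)
        if trace:
            sum_P[absent] += p[absent]
            cnt_P[absent] += 1
            if keep_step_log:
                log_rows[t] = p
        # single multinomial draw via inverse-CDF on the condensed vector
        pick = int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))
        pick = min(pick, q - 1)
        absent[pick] = False
        u, v = int(iu_i[pick]), int(iu_j[pick])
        order[t] = (u, v)
        A[u, v] = A[v, u] = 1
        k_deg[u] += 1
        k_deg[v] += 1
        if dynamic_matching:
            # adding (u, v) only changes neighbourhoods of u and v, so only
            # rows/columns u and v of the matching matrix can change
            rows = _matching_rows(A, k_deg, np.array([u, v]))
            Fm[u, :] = rows[0]
            Fm[:, u] = rows[0]
            Fm[v, :] = rows[1]
            Fm[:, v] = rows[1]
            Fm[u, v] = Fm[v, u] = rows[0][v]

    mean_vec = np.divide(sum_P, cnt_P, out=np.zeros(q), where=cnt_P > 0)
    tr = GrowthTrace(
        edge_order=order,
        mean_P=square(mean_vec, n),
        step_count_P=square(cnt_P, n),
        completed=True,
        tracked=trace,
        prob_sum_max_abs_err=max_err if debug else None,
        step_log=log_rows,
    )
    return BinaryNetwork(A), tr


def mean_connection_probability(trace: GrowthTrace) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-step connection probability and its step-count bookkeeping.

    A pair added at step t averages over steps 1..t; a never-added pair
    averages over all m steps.
    """
    if not trace.completed:
        raise ValueError("trace comes from an incomplete run")
    if not trace.tracked:
        raise ValueError("probabilities were not tracked for this run "
                         "(grow with trace=True)")
    return trace.mean_P, trace.step_count_P
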