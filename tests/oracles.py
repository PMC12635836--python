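"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — explicit loops over sets and
pairs — and stays independent of the code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_matching(A: np.ndarray) -> np.ndarray:
    """Matching index by explicit set arithmetic per pair."""
    n = A.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ni = {k for k in range(n) if A[i, k] and k != j}
            nj = {k for k in range(n) if A[j, k] and k != i}
            union = ni | nj
            out[i, j] = len(ni & nj) / len(union) if union else 0.0
    return out


def brute_clustering(A: np.ndarray) -> np.ndarray:
    """Watts–Strogatz local clustering by neighbour-pair enumeration."""
    n = A.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = [u for u in range(n) if A[v, u]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(A[a, b] for a, b in itertools.combinations(nb, 2))
        out[v] = 2 * links / (k * (k - 1))
    return out


def brute_betweenness(A: np.ndarray) -> np.ndarray:
    """Betweenness by exhaustive shortest-path enumeration (BFS + DFS).

    Raw dependency counts over unordered pairs s < t, unreachable pairs
    contribute nothing.
    """
    import networkx as nx

    n = A.shape[0]
    G = nx.from_numpy_array(A)
    out = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        for p in paths:
            for v in p[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


def brute_ks(x, y) -> float:
    """Two-sample KS via explicit ECDF evaluation at pooled points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


def brute_pearson(a, b) -> float:
    """Textbook covariance / sigma formula, computed longhand."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    am, bm = a.mean(), b.mean()
    cov = np.mean((a - am) * (b - bm))
    sa = np.sqrt(np.mean((a - am) ** 2))
    sb = np.sqrt(np.mean((b - bm) ** 2))
    return cov / (sa * sb)


def brute_spearman(a, b) -> float:
    """Average-rank assignment followed by Pearson on the ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size)
        i = 0
        sv = v[order]
        while i < v.size:
            j = i
            while j < v.size and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2 + 1
            i = j
        return ranks
    return brute_pearson(avg_ranks(a), avg_ranks(b))


def reference_matching_growth(emb, params, m_target, seed):
    """Naive matching-model growth: matrix-level weights recomputed from
    scratch every step, same sampling scheme as the engine (one uniform
    draw per step, inverse-CDF on the condensed cumulative vector)."""
    from gnmlab._pairs import condense, triu_pairs
    from gnmlab.engine import F_EPS

    n = emb.n
    rng = np.random.default_rng(seed)
    d = condense(emb.D)
    iu_i, iu_j = triu_pairs(n)
    A = np.zeros((n, n), dtype=np.int8)
    absent = np.ones(d.size, dtype=bool)
    order = []
    for _ in range(m_target):
        td = np.exp(-params.eta * (d - d[absent].min()))
        f = condense(brute_matching(A))
        if f[absent].max() <= F_EPS:
            w = td
        else:
            fc = np.maximum(f, F_EPS)
            if params.gamma > 0:
                ext = fc[absent].max()
            elif params.gamma < 0:
                ext = fc[absent].min()
            else:
                ext = 1.0
            tf = (fc / ext) ** params.gamma if params.gamma != 0 \
                else np.ones_like(fc)
            w = td + params.alpha * tf if params.form == "additive" else td * tf
        w = np.where(absent, w, 0.0)
        p = w / w.sum()
        pick = int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))
        pick = min(pick, d.size - 1)
        absent[pick] = False
        u, v = int(iu_i[pick]), int(iu_j[pick])
        order.append((u, v))
        A[u, v] = A[v, u] = 1
    return np.asarray(order), A
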