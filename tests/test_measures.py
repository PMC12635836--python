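import numpy as np
import pytest
from scipy import stats

import gnmlab as g
from gnmlab.measures import (alt_measures, degree_correlation,
                             distance_binned_recovery, ks_stat, max_ks,
                             recovery_overlap, topology_vectors)

from oracles import (brute_betweenness, brute_clustering, brute_ks,
                     brute_spearman)


def embed_n(n, seed=0, scale=100.0):
    return g.make_embedding(n, "cloud", scale, seed=seed)


# --- topology vectors -------------------------------------------------------

def test_triangle_topology():
    emb = embed_n(3)
    net = g.BinaryNetwork.from_edges(3, [(0, 1), (0, 2), (1, 2)])
    tv = topology_vectors(net, emb)
    assert np.array_equal(tv.degree, [2, 2, 2])
    assert np.allclose(tv.clustering, 1.0)
    assert np.allclose(tv.betweenness, 0.0)


def test_path_betweenness_hand_computed():
    emb = embed_n(3)
    net = g.BinaryNetwork.from_edges(3, [(0, 1), (1, 2)])
    tv = topology_vectors(net, emb)
    assert tv.betweenness[1] == pytest.approx(1.0)   # one dependent pair
    assert np.allclose(tv.clustering, 0.0)


def test_handshake_lemma(random_graphs8):
    for net in random_graphs8[:40]:
        emb = embed_n(net.n, seed=net.n)
        tv = topology_vectors(net, emb)
        assert tv.degree.sum() == 2 * net.m
        assert tv.edge_lengths.size == net.m


def test_clustering_betweenness_match_bruteforce(random_graphs8):
    """igraph-backed nodal vectors equal exhaustive enumeration, n <= 8."""
    for net in random_graphs8:
        emb = embed_n(net.n, seed=net.n)
        tv = topology_vectors(net, emb)
        assert np.allclose(tv.clustering, brute_clustering(net.A), atol=1e-12)
        assert np.allclose(tv.betweenness, brute_betweenness(net.A),
                           atol=1e-9)


# --- KS statistic -----------------------------------------------------------

def test_ks_identical_and_disjoint():
    assert ks_stat([1, 2, 2, 3], [1, 2, 2, 3]) == 0.0
    assert ks_stat([1, 2, 3], [10, 11]) == 1.0


def test_ks_textbook_example():
    assert ks_stat([1, 2, 3], [2, 3, 4]) == pytest.approx(1 / 3)


def test_ks_empty_sample_error():
    with pytest.raises(ValueError):
        ks_stat([], [1.0])


def test_ks_matches_independent_implementations():
    """Pooled-ECDF statistic agrees with scipy and with a brute-force
    second code path on 1,000 random sample pairs."""
    rng = np.random.default_rng(17)
    for i in range(1000):
        nx_ = int(rng.integers(3, 200))
        ny = int(rng.integers(3, 200))
        x = rng.normal(size=nx_)
        y = rng.normal(loc=rng.uniform(-1, 1), size=ny)
        if i % 3 == 0:                       # exercise heavy ties
            x = np.round(x)
            y = np.round(y)
        d = ks_stat(x, y)
        assert d == pytest.approx(
            stats.ks_2samp(x, y, method="asymp").statistic, abs=1e-12)
        if i < 200:
            assert d == pytest.approx(brute_ks(x, y), abs=1e-12)


def test_max_ks_symmetry_and_identity(emb60, target60):
    net = target60.network
    ks = max_ks(net, net, emb60)
    assert all(v == 0 for v in ks.values())
    other = g.plant_target(emb60, 180, decay=0.0, seed=9).network
    ab = max_ks(net, other, emb60)
    ba = max_ks(other, net, emb60)
    for k in ("KS_k", "KS_c", "KS_b", "KS_e", "maxKS"):
        assert ab[k] == ba[k]
    assert ab["maxKS"] == max(ab["KS_k"], ab["KS_c"], ab["KS_b"], ab["KS_e"])


# --- recovery / overlap -----------------------------------------------------

def test_recovery_identity_and_disjoint():
    a = g.BinaryNetwork.from_edges(5, [(0, 1), (1, 2), (2, 3)])
    r = recovery_overlap(a, a)
    assert (r["R"], r["jaccard"], r["fdr"]) == (1.0, 1.0, 0.0)
    b = g.BinaryNetwork.from_edges(5, [(0, 4), (1, 4), (2, 4)])
    r = recovery_overlap(b, a)
    assert (r["R"], r["jaccard"], r["fdr"]) == (0.0, 0.0, 1.0)


def test_recovery_hand_example():
    # target {ab, bc, cd}, model {ab, bc, ce}
    target = g.BinaryNetwork.from_edges(5, [(0, 1), (1, 2), (2, 3)])
    model = g.BinaryNetwork.from_edges(5, [(0, 1), (1, 2), (2, 4)])
    r = recovery_overlap(model, target)
    assert r["R"] == pytest.approx(2 / 3)
    assert r["jaccard"] == pytest.approx(2 / 4)
    assert r["fdr"] == pytest.approx(1 / 3)


def test_recovery_counting_identities(emb60, target60):
    model = g.plant_target(emb60, 180, decay=0.1, seed=77).network
    r = recovery_overlap(model, target60.network)
    assert r["R"] * target60.network.m == pytest.approx(r["n_common"])
    assert (1 - r["fdr"]) * model.m == pytest.approx(r["n_common"])


# --- degree correlation -----------------------------------------------------

def test_degree_correlation_identity_and_reversal():
    a = g.BinaryNetwork.from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2)])
    assert degree_correlation(a, a) == pytest.approx(1.0)


def test_degree_correlation_with_ties_matches_rank_oracle(emb60):
    a = g.plant_target(emb60, 150, decay=0.05, seed=1).network
    b = g.plant_target(emb60, 150, decay=0.05, seed=2).network
    rho = degree_correlation(a, b)
    assert rho == pytest.approx(brute_spearman(a.degree, b.degree), abs=1e-12)
    r = degree_correlation(a, b, method="pearson")
    assert r == pytest.approx(stats.pearsonr(a.degree, b.degree).statistic)


def test_degree_correlation_zero_variance_flagged():
    ring = g.BinaryNetwork.from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
    with pytest.warns(UserWarning, match="zero-variance"):
        assert np.isnan(degree_correlation(ring, ring))


# --- alternative measures ---------------------------------------------------

def test_alt_measures_identity_zero(emb60, target60):
    out = alt_measures(target60.network, target60.network, emb60)
    for k, v in out.items():
        assert v == pytest.approx(0.0, abs=1e-10), k


def test_alt_measures_symmetric(emb60):
    a = g.plant_target(emb60, 150, decay=0.05, seed=5).network
    b = g.plant_target(emb60, 150, decay=0.0, seed=6).network
    ab = alt_measures(a, b, emb60)
    ba = alt_measures(b, a, emb60)
    for k in ab:
        assert ab[k] == pytest.approx(ba[k], abs=1e-9)


def test_alt_measures_toy_components_longhand():
    """Each component reproduced from first principles on two 10-node toys."""
    emb = embed_n(10, seed=3)
    a = g.plant_target(emb, 20, decay=0.0, seed=10).network
    b = g.plant_target(emb, 20, decay=0.0, seed=11).network
    out = alt_measures(a, b, emb)
    ta = topology_vectors(a, emb)
    tb = topology_vectors(b, emb)
    # max_rd longhand
    from oracles import brute_pearson
    rds = []
    for va, vb in [(ta.degree, tb.degree), (ta.clustering, tb.clustering),
                   (ta.betweenness, tb.betweenness),
                   (ta.node_mean_length, tb.node_mean_length)]:
        rds.append(1 - brute_pearson(va, vb))
    assert out["max_rd"] == pytest.approx(max(rds), abs=1e-10)
    # TF_diff longhand from explicit 4x4 correlation matrices
    fa = np.vstack([ta.degree, ta.clustering, ta.betweenness,
                    ta.node_mean_length])
    fb = np.vstack([tb.degree, tb.clustering, tb.betweenness,
                    tb.node_mean_length])
    ca = np.array([[brute_pearson(x, y) for y in fa] for x in fa])
    cb = np.array([[brute_pearson(x, y) for y in fb] for x in fb])
    assert out["TF_diff"] == pytest.approx(
        np.sqrt(((ca - cb) ** 2).sum()), abs=1e-9)


def test_max_rmse_invariant_to_common_affine_transform():
    """Joint min-max rescaling absorbs any shared affine transform of the
    raw vectors, so the RMSE component is unchanged."""
    rng = np.random.default_rng(8)
    va = rng.uniform(0, 5, 30)
    vb = rng.uniform(0, 5, 30)

    def rmse(x, y):
        lo, hi = min(x.min(), y.min()), max(x.max(), y.max())
        sx, sy = (x - lo) / (hi - lo), (y - lo) / (hi - lo)
        return np.sqrt(np.mean((sx - sy) ** 2))

    base = rmse(va, vb)
    assert rmse(3 * va + 7, 3 * vb + 7) == pytest.approx(base, abs=1e-12)


# --- binned recovery --------------------------------------------------------

def test_binned_recovery_identity(emb60, target60):
    rows = distance_binned_recovery(target60.network, target60.network, emb60)
    for r in rows:
        if r["valid"]:
            assert r["recovery"] == 1.0


def test_binned_recovery_manual_toy():
    coords = np.array([[0., 0, 0], [10, 0, 0], [0, 10, 0],
                       [100, 0, 0], [0, 100, 0]])
    emb = g.SpatialEmbedding.from_coords(coords, neighbor_k=2)
    target = g.BinaryNetwork.from_edges(5, [(0, 1), (0, 2), (3, 4)])
    model = g.BinaryNetwork.from_edges(5, [(0, 1), (0, 2), (1, 2)])
    rows = distance_binned_recovery(model, target, emb)
    assert rows[0]["recovery"] == 1.0          # both short edges recovered
    assert not rows[1]["valid"]                # no mid-range target edges
    assert rows[2]["recovery"] == 0.0          # long edge missed
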