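import numpy as np
import pytest

import gnmlab as g
from gnmlab.synth import feature_similarity, make_cohort, plant_target, \
    smooth_random_features

from oracles import brute_pearson


# --- neighbour-smoothed random features ------------------------------------

def test_constant_column_is_fixed_point(emb60):
    init = np.full((emb60.n, 1), 0.37)
    ft = smooth_random_features(emb60, n_smooth=7, seed=0, init=init)
    assert np.allclose(ft.values, 0.37)


def test_zero_rounds_returns_raw_draws(emb60):
    a = smooth_random_features(emb60, n_features=4, n_smooth=0, seed=3)
    rng = np.random.default_rng(3)
    assert np.array_equal(a.values, rng.uniform(0, 1, size=(emb60.n, 4)))


def test_four_cycle_one_round_hand_computed():
    """One synchronous round on a 4-cycle reproduces per-node neighbour
    means computed by hand."""
    coords = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.]])
    ring = np.array([[0, 1, 0, 1], [1, 0, 1, 0],
                     [0, 1, 0, 1], [1, 0, 1, 0]])
    emb = g.SpatialEmbedding(node_ids=list("abcd"), coords=coords,
                             D=g.SpatialEmbedding.from_coords(coords).D,
                             neighbor_graph=ring)
    # alternating values: both neighbours hold the opposite value, so a
    # synchronous round swaps the pattern (a sequential sweep would not)
    alt = np.array([0.0, 1.0, 0.0, 1.0])[:, None]
    out = smooth_random_features(emb, n_smooth=1, seed=0, init=alt)
    assert np.allclose(out.values.ravel(), [1.0, 0.0, 1.0, 0.0])
    # (0,1,1,0) around the ring: every node sees one 0 and one 1
    mixed = np.array([0.0, 1.0, 1.0, 0.0])[:, None]
    out2 = smooth_random_features(emb, n_smooth=1, seed=0, init=mixed)
    assert np.allclose(out2.values.ravel(), 0.5)
    # and the all-0.5 state is a fixed point of any further round
    out3 = smooth_random_features(emb, n_smooth=4, seed=0, init=mixed)
    assert np.allclose(out3.values.ravel(), 0.5)


def test_isolated_node_rejected(emb60):
    ng = emb60.neighbor_graph.copy()
    ng[0, :] = 0
    ng[:, 0] = 0
    emb = g.SpatialEmbedding(node_ids=emb60.node_ids, coords=emb60.coords,
                             D=emb60.D, neighbor_graph=ng)
    with pytest.raises(ValueError, match="isolated"):
        smooth_random_features(emb, seed=0)


def test_smoothing_contracts_variance():
    """Each averaging round shrinks (or preserves) every column's variance."""
    rng = np.random.default_rng(11)
    for trial in range(20):
        emb = g.make_embedding(int(rng.integers(10, 40)), "cloud", 50.0,
                              seed=trial)
        prev = smooth_random_features(emb, n_features=10, n_smooth=0,
                                      seed=trial).values
        for r in range(1, 4):
            cur = smooth_random_features(emb, n_features=10, n_smooth=r,
                                         seed=trial).values
            assert np.all(cur.var(axis=0) <= prev.var(axis=0) + 1e-12)
            prev = cur


# --- interregional similarity ----------------------------------------------

def test_similarity_boundary_cases():
    vals = np.array([[1.0, 2.0, 3.0],     # node 1 identical profile shape
                     [2.0, 4.0, 6.0],     # perfectly correlated with node 0
                     [3.0, 2.0, 1.0]])    # exactly anticorrelated
    sim = feature_similarity(g.FeatureTable(values=vals))
    assert sim.F[0, 1] == pytest.approx(1.0)
    assert sim.F[0, 2] == pytest.approx(0.0)


def test_similarity_matches_longhand_pearson():
    vals = np.array([[1.0, 2.0, 3.0, 4.0],
                     [1.0, 2.0, 3.0, 5.0],
                     [4.0, 1.0, 2.0, 2.0]])
    sim = feature_similarity(g.FeatureTable(values=vals))
    r = brute_pearson(vals[0], vals[1])
    assert sim.F[0, 1] == pytest.approx((r + 1) / 2, abs=1e-12)


def test_orientation_flip_is_exact_complement(emb60):
    ft = smooth_random_features(emb60, seed=5)
    s = feature_similarity(ft, orientation="similarity")
    d = feature_similarity(ft, orientation="distance")
    assert np.allclose(s.F + d.F, 1.0, atol=1e-12)
    assert np.allclose(s.flipped().F, d.F, atol=1e-12)


def test_zero_variance_profile_names_node():
    vals = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [0.0, 1.0, 2.0]])
    with pytest.raises(ValueError, match="node 1"):
        feature_similarity(g.FeatureTable(values=vals))


def test_similarity_bounds_and_symmetry(emb60):
    sim = feature_similarity(smooth_random_features(emb60, seed=9))
    assert np.allclose(sim.F, sim.F.T)
    assert sim.F.min() >= 0 and sim.F.max() <= 1


# --- planted targets --------------------------------------------------------

def test_uniform_graph_at_zero_decay(emb60):
    pt = plant_target(emb60, m=100, decay=0.0, seed=1)
    assert pt.network.m == 100
    assert pt.n_planted == 0


def test_planted_edges_respect_cutoff(emb60, target60):
    lengths = [emb60.D[i, j] for i, j in target60.planted_long_edges]
    assert len(lengths) == 15
    assert min(lengths) >= 90.0
    assert target60.network.m == 180


def test_infeasible_hub_spec_rejected(emb60):
    with pytest.raises(ValueError, match="infeasible"):
        plant_target(emb60, m=100, decay=0.0,
                     hub_spec={"n_hubs": 3, "long_cutoff": 90.0,
                               "n_planted": 50}, seed=0)


def test_decay_shortens_edges(emb60):
    """Monte-Carlo: decayed sampling yields shorter mean edges than uniform."""
    mean_len = {}
    for lam in (0.0, 0.5):
        lens = []
        for s in range(50):
            pt = plant_target(emb60, m=120, decay=lam, seed=1000 + s)
            lens.append(pt.network.edge_lengths(emb60.D).mean())
        mean_len[lam] = np.mean(lens)
    assert mean_len[0.5] < mean_len[0.0]


def test_distance_vs_inclusion_frequency_negative():
    from scipy import stats
    emb = g.make_embedding(60, "shell", 100.0, seed=40)
    counts = np.zeros(emb.d_condensed.size)
    for s in range(100):
        pt = plant_target(emb, m=150, decay=0.1, seed=s)
        counts += pt.network.condensed()
    rho = stats.spearmanr(emb.d_condensed, counts).statistic
    assert rho < 0


# --- cohorts ---------------------------------------------------------------

def test_cohort_zero_swaps_identical(emb60, target60):
    subs = make_cohort(target60.network, emb60, n_subjects=3, n_swaps=0,
                       seed=2)
    for s in subs:
        assert s == target60.network


def test_cohort_exact_overlap_and_density(emb60, target60):
    base = target60.network
    m = base.m
    for t in (10, 60):
        subs = make_cohort(base, emb60, n_subjects=4, n_swaps=t, seed=3)
        for s in subs:
            assert s.m == m
            assert base.overlap(s) == pytest.approx((m - t) / m, abs=1e-12)


def test_cohort_jaccard_decreases_with_swaps(emb60, target60):
    """Pairwise subject overlap shrinks as more edges are relocated."""
    base = target60.network
    m = base.m
    med = []
    for t in (0, m // 10, m // 2):
        jac = []
        for s in range(20):
            a, b = make_cohort(base, emb60, 2, t, seed=100 + s)
            jac.append(g.recovery_overlap(a, b)["jaccard"])
        med.append(np.mean(jac))
    assert med[0] == pytest.approx(1.0)
    assert med[0] > med[1] > med[2]
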