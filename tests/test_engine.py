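import numpy as np
import pytest
from hypothesis import given, strategies as st

import gnmlab as g
from gnmlab.engine import (F_EPS, GNMParams, ModelSpec,
                           connection_probabilities, grow_network,
                           matching_index, mean_connection_probability,
                           wiring_weights)
from gnmlab._pairs import condense

from oracles import brute_matching, reference_matching_growth


def tiny_embedding():
    coords = np.array([[0., 0, 0], [1, 0, 0], [0, 2, 0]])
    return g.SpatialEmbedding.from_coords(coords, neighbor_k=2)


# --- wiring weights ---------------------------------------------------------

def test_flat_weights_when_eta_and_alpha_zero():
    emb = g.make_embedding(10, "cloud", 50.0, seed=0)
    F = np.full((10, 10), 0.5)
    np.fill_diagonal(F, 0)
    w, pairs = wiring_weights(emb.D, F, np.zeros((10, 10)),
                              GNMParams(eta=0.0, gamma=1.0, alpha=0.0))
    assert np.allclose(w, 1.0)
    assert pairs.shape == (45, 2)


def test_multiplicative_gamma_zero_reduces_to_distance_term():
    emb = g.make_embedding(8, "cloud", 50.0, seed=1)
    rng = np.random.default_rng(2)
    F = rng.uniform(0.2, 0.9, (8, 8))
    F = (F + F.T) / 2
    np.fill_diagonal(F, 0)
    p_mult = GNMParams(eta=0.05, gamma=0.0, form="multiplicative")
    p_spat = GNMParams(eta=0.05)
    w1, _ = wiring_weights(emb.D, F, np.zeros((8, 8)), p_mult)
    w2, _ = wiring_weights(emb.D, None, np.zeros((8, 8)), p_spat)
    assert np.allclose(w1, w2, atol=1e-14)


def test_three_node_longhand_weights():
    """D = [[0,1,2],[1,0,3],[2,3,0]], eta=1: weights (1, 1/e, 1/e^2)."""
    D = np.array([[0., 1, 2], [1, 0, 3], [2, 3, 0]])
    w, pairs = wiring_weights(D, None, np.zeros((3, 3)), GNMParams(eta=1.0))
    expect = {(0, 1): 1.0, (0, 2): np.exp(-1), (1, 2): np.exp(-2)}
    for wi, (i, j) in zip(w, pairs):
        assert wi == pytest.approx(expect[(i, j)], rel=1e-12)


def test_powerlaw_rejects_zero_distance():
    D = np.array([[0., 0, 1], [0, 0, 1], [1, 1, 0]])
    with pytest.raises(ValueError):
        wiring_weights(D, None, np.zeros((3, 3)),
                       GNMParams(eta=1.0, decay="powerlaw"))


def test_multiplicative_alpha_rejected():
    with pytest.raises(ValueError, match="alpha"):
        GNMParams(eta=1.0, gamma=2.0, alpha=3.0, form="multiplicative")


def test_logspace_matches_naive_evaluation():
    """Ratio-form evaluation equals direct F^gamma/max(F^gamma) wherever
    the naive form does not underflow."""
    rng = np.random.default_rng(33)
    for _ in range(30):
        n = 12
        emb = g.make_embedding(n, "cloud", 50.0, seed=int(rng.integers(1e6)))
        F = rng.uniform(0.05, 1.0, (n, n))
        F = (F + F.T) / 2
        np.fill_diagonal(F, 0)
        eta = rng.uniform(0, 2)
        gamma = rng.uniform(-30, 30)
        alpha = rng.uniform(0, 10)
        A = np.zeros((n, n))
        w, pairs = wiring_weights(emb.D, F, A,
                                  GNMParams(eta=eta, gamma=gamma, alpha=alpha))
        # naive direct evaluation
        d = condense(emb.D)
        f = np.maximum(condense(F), F_EPS)
        td = np.exp(-eta * d)
        td = td / td.max()
        tf = f ** gamma
        ext = tf.max()
        naive = td + alpha * tf / ext
        finite = np.isfinite(naive) & (tf > 0)
        assert np.allclose(w[finite], naive[finite], rtol=1e-9)


# --- probabilities ----------------------------------------------------------

def test_uniform_weights_uniform_probabilities():
    p = connection_probabilities(np.ones(7))
    assert np.allclose(p, 1 / 7)


def test_probabilities_sum_to_one():
    rng = np.random.default_rng(0)
    w = rng.uniform(0, 5, 100)
    assert connection_probabilities(w).sum() == pytest.approx(1.0, abs=1e-12)


def test_probabilities_direct_division():
    p = connection_probabilities(np.array([2.0, 1.0, 1.0]))
    assert np.allclose(p, [0.5, 0.25, 0.25])


def test_all_zero_weights_is_error():
    with pytest.raises(ValueError):
        connection_probabilities(np.zeros(4))


# --- matching index ---------------------------------------------------------

def test_matching_empty_network():
    assert np.all(matching_index(np.zeros((5, 5))) == 0)


def test_matching_triangle_and_star():
    K3 = np.ones((3, 3)) - np.eye(3)
    m = matching_index(K3)
    assert m[0, 1] == m[0, 2] == m[1, 2] == 1.0
    star = np.zeros((4, 4))
    star[0, 1:] = star[1:, 0] = 1
    ms = matching_index(star)
    assert ms[1, 2] == ms[1, 3] == ms[2, 3] == 1.0   # leaves share the hub
    assert ms[0, 1] == ms[0, 2] == ms[0, 3] == 0.0   # hub vs leaf: empty set


def test_matching_matches_bruteforce(random_graphs8):
    for net in random_graphs8[:60]:
        assert np.allclose(matching_index(net.A), brute_matching(net.A),
                           atol=1e-12)


# --- growth -----------------------------------------------------------------

def test_zero_target_edges():
    emb = tiny_embedding()
    net, tr = grow_network(emb, ModelSpec(), 0, seed=0)
    assert net.m == 0
    assert tr.edge_order.shape == (0, 2)


def test_capacity_check():
    emb = tiny_embedding()
    with pytest.raises(ValueError):
        grow_network(emb, ModelSpec(), 4, seed=0)


def test_matching_first_step_equals_spatial(emb60):
    """With no edges yet the matching term carries no signal, so step-1
    probabilities coincide with the spatial model's."""
    p_match = ModelSpec(params=GNMParams(eta=0.02, gamma=3.0, alpha=2.0),
                        feature_source="matching")
    p_spat = ModelSpec(params=GNMParams(eta=0.02))
    A0 = np.zeros((emb60.n, emb60.n))
    w_m, _ = wiring_weights(emb60.D, np.zeros_like(A0), A0, p_match.params)
    w_s, _ = wiring_weights(emb60.D, None, A0, p_spat.params)
    pm = connection_probabilities(w_m)
    ps = connection_probabilities(w_s)
    assert np.max(np.abs(pm - ps)) < 1e-6
    # identical seeds then pick the identical first edge
    net_m, tr_m = grow_network(emb60, p_match, 1, seed=9)
    net_s, tr_s = grow_network(emb60, p_spat, 1, seed=9)
    assert np.array_equal(tr_m.edge_order, tr_s.edge_order)


def test_stronger_decay_shortens_generated_edges(emb_small10):
    means = {}
    for eta in (0.0, 2.0):
        lens = []
        for s in range(20):
            net, _ = grow_network(emb_small10,
                                  ModelSpec(params=GNMParams(eta=eta)),
                                  300, seed=500 + s, trace=False)
            lens.append(net.edge_lengths(emb_small10.D).mean())
        means[eta] = np.mean(lens)
    assert means[2.0] < means[0.0]


def test_growth_invariants_and_determinism(emb60):
    spec = ModelSpec(params=GNMParams(eta=0.05))
    net1, tr1 = grow_network(emb60, spec, 120, seed=4, debug=True)
    net2, tr2 = grow_network(emb60, spec, 120, seed=4, debug=True)
    assert net1.m == 120
    assert np.array_equal(net1.A, net1.A.T)
    assert np.all(np.diag(net1.A) == 0)
    assert np.array_equal(tr1.edge_order, tr2.edge_order)
    assert tr1.prob_sum_max_abs_err <= 1e-12


def test_matching_growth_equals_from_scratch_reference(emb60):
    """The incrementally maintained matching matrix drives the same edge
    sequence as a naive implementation recomputing it from scratch."""
    params = GNMParams(eta=0.03, gamma=1.5, alpha=2.0)
    spec = ModelSpec(params=params, feature_source="matching")
    net, tr = grow_network(emb60, spec, 40, seed=12)
    ref_order, ref_A = reference_matching_growth(emb60, params, 40, seed=12)
    assert np.array_equal(tr.edge_order, ref_order)
    assert np.array_equal(net.A, ref_A)


def test_static_path_matches_stepwise_distribution():
    """Sampling-without-replacement shortcut draws edge sets from the same
    distribution as the sequential reference loop (spatial model)."""
    coords = np.array([[0., 0, 0], [1, 0, 0], [2.5, 0, 0], [0, 1.5, 0]])
    emb = g.SpatialEmbedding.from_coords(coords, neighbor_k=2)
    spec = ModelSpec(params=GNMParams(eta=0.8))
    counts = {"static": {}, "stepwise": {}}
    n_rep = 4000
    for method in counts:
        for s in range(n_rep):
            net, _ = grow_network(emb, spec, 2, seed=s, trace=False,
                                  method=method)
            key = tuple(map(tuple, net.edges()))
            counts[method][key] = counts[method].get(key, 0) + 1
    keys = set(counts["static"]) | set(counts["stepwise"])
    for k in keys:
        fa = counts["static"].get(k, 0) / n_rep
        fb = counts["stepwise"].get(k, 0) / n_rep
        assert abs(fa - fb) < 0.03


def test_mean_probability_bookkeeping(emb60):
    spec = ModelSpec(params=GNMParams(eta=0.05))
    net, tr = grow_network(emb60, spec, 30, seed=7, keep_step_log=True)
    mean_P, counts = mean_connection_probability(tr)
    assert mean_P.min() >= 0 and mean_P.max() <= 1
    log = tr.step_log
    from gnmlab._pairs import pair_index
    added_at = {}
    for t, (i, j) in enumerate(tr.edge_order):
        added_at[int(pair_index(np.array([i]), np.array([j]), emb60.n)[0])] = t
    q = log.shape[1]
    for k in range(0, q, 37):
        if k in added_at:
            t0 = added_at[k]
            expect = log[:t0 + 1, k].mean()
            assert counts[tuple(tr.edge_order[t0])] == t0 + 1
        else:
            expect = log[:, k].mean()
        i, j = np.triu_indices(emb60.n, 1)
        assert mean_P[i[k], j[k]] == pytest.approx(expect, abs=1e-15)


def test_mean_probability_requires_tracking(emb60):
    net, tr = grow_network(emb60, ModelSpec(), 10, seed=0, trace=False,
                           method="stepwise")
    with pytest.raises(ValueError):
        mean_connection_probability(tr)


@given(st.integers(min_value=0, max_value=10_000))
def test_probability_conservation_any_seed(seed):
    """Per-step probabilities over absent pairs always sum to one."""
    emb = g.make_embedding(12, "cloud", 30.0, seed=99)
    spec = ModelSpec(params=GNMParams(eta=0.1, gamma=2.0, alpha=1.0),
                     feature_source="matching")
    grow_network(emb, spec, 20, seed=seed, debug=True)
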