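"""Graph metrics against brute-force oracles; small-world fixed points."""

import networkx as nx
import numpy as np
import pytest

from brainphen.connectivity import ConnectivityMatrix
from brainphen.graphmetrics import (characteristic_path_length,
                                    global_efficiency, lattice_null,
                                    local_efficiency, mean_strength,
                                    participant_network_features, random_null,
                                    small_world_propensity,
                                    weighted_clustering)
from conftest import random_weighted_graph

PHI_FIXED_POINT = 1.0 - np.sqrt(0.5)  # ~0.2929


# ---------------------------------------------------------------- oracles
def floyd_warshall_oracle(w):
    """All-pairs shortest paths with edge length 1/weight; pure triple loop."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering_oracle(w):
    """Onnela clustering by exhaustive triple enumeration."""
    n = w.shape[0]
    if not w.any():
        return 0.0
    what = w / w.max()
    c = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        k = nbrs.size
        if k < 2:
            continue
        total = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h:
                    total += (what[i, j] * what[i, h] * what[j, h]) ** (1 / 3)
        c[i] = total / (k * (k - 1))
    return float(c.mean())


def path_length_oracle(w):
    d = floyd_warshall_oracle(w)
    off = ~np.eye(w.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    return float(d[finite].mean())


def global_efficiency_oracle(w):
    d = floyd_warshall_oracle(w)
    off = ~np.eye(w.shape[0], dtype=bool)
    inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return float(inv[off].mean())


def local_efficiency_oracle(w):
    n = w.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size >= 2:
            eff[i] = global_efficiency_oracle(w[np.ix_(nbrs, nbrs)])
    return float(eff.mean())


# ------------------------------------------------------------- clustering
def test_unweighted_triangle_clusters_fully():
    w = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    assert weighted_clustering(w) == pytest.approx(1.0)


def test_star_graph_has_zero_clustering():
    w = np.zeros((5, 5))
    w[0, 1:] = w[1:, 0] = 1.0
    assert weighted_clustering(w) == pytest.approx(0.0)


def test_five_node_weighted_graph_matches_triple_enumeration():
    w = np.zeros((5, 5))
    edges = [(0, 1, 0.9), (0, 2, 0.4), (1, 2, 0.7), (1, 3, 0.2),
             (2, 4, 0.6), (3, 4, 1.0)]
    for i, j, v in edges:
        w[i, j] = w[j, i] = v
    assert weighted_clustering(w) == pytest.approx(clustering_oracle(w),
                                                   abs=1e-12)


# ------------------------------------------------------------ path length
def test_two_node_reciprocal_weight():
    w = np.array([[0.0, 0.5], [0.5, 0.0]])
    L, reachable = characteristic_path_length(w)
    assert L == pytest.approx(2.0)
    assert reachable


def test_unweighted_complete_graph_unit_length():
    w = 1.0 - np.eye(6)
    L, _ = characteristic_path_length(w)
    assert L == pytest.approx(1.0)


def test_random_graph_matches_floyd_warshall(rng):
    w = random_weighted_graph(rng, 10, p=0.5)
    L, _ = characteristic_path_length(w)
    assert L == pytest.approx(path_length_oracle(w), abs=1e-9)


def test_edgeless_graph_rejected():
    with pytest.raises(ValueError, match="no edges"):
        characteristic_path_length(np.zeros((4, 4)))


def test_disconnected_graph_flagged(rng):
    w = np.zeros((5, 5))
    w[0, 1] = w[1, 0] = 0.8
    w[2, 3] = w[3, 2] = 0.5
    L, reachable = characteristic_path_length(w)
    assert not reachable
    assert L == pytest.approx((1 / 0.8 + 1 / 0.5) / 2)


# ------------------------------------------------------------ efficiencies
def test_complete_graph_unit_global_efficiency():
    for n in (3, 5, 8):
        assert global_efficiency(1.0 - np.eye(n)) == pytest.approx(1.0)


def test_edgeless_graph_zero_efficiency():
    assert global_efficiency(np.zeros((4, 4))) == 0.0
    assert local_efficiency(np.zeros((4, 4))) == 0.0
    assert mean_strength(np.zeros((4, 4))) == 0.0


def test_random_graph_efficiencies_match_oracles(rng):
    w = random_weighted_graph(rng, 12, p=0.45)
    assert global_efficiency(w) == pytest.approx(global_efficiency_oracle(w),
                                                 abs=1e-9)
    assert local_efficiency(w) == pytest.approx(local_efficiency_oracle(w),
                                                abs=1e-9)
    assert mean_strength(w) == pytest.approx(w.sum(axis=0).mean(), abs=1e-12)


# ------------------------------------------------------------- null models
def ring_lattice(n, k):
    return nx.to_numpy_array(nx.watts_strogatz_graph(n, k, 0.0, seed=1))


def test_lattice_null_fixes_ring_lattice():
    w = ring_lattice(30, 4)
    latt, warn = lattice_null(w)
    assert not warn
    assert weighted_clustering(latt) == pytest.approx(weighted_clustering(w),
                                                      abs=1e-9)
    assert characteristic_path_length(latt)[0] == pytest.approx(
        characteristic_path_length(w)[0], abs=1e-9)


def test_nulls_conserve_total_weight(rng):
    w = random_weighted_graph(rng, 15, p=0.4)
    latt, _ = lattice_null(w)
    rnd = random_null(w, seed=3)
    assert latt.sum() == pytest.approx(w.sum(), abs=1e-12)
    assert rnd.sum() == pytest.approx(w.sum(), abs=1e-12)
    # same weight multiset
    np.testing.assert_allclose(np.sort(latt[latt > 0]), np.sort(w[w > 0]))
    np.testing.assert_allclose(np.sort(rnd[rnd > 0]), np.sort(w[w > 0]))


def test_random_null_preserves_degree_sequence_exactly(rng):
    w = random_weighted_graph(rng, 20, p=0.25)
    for seed in range(5):
        rnd = random_null(w, seed=seed)
        np.testing.assert_array_equal((rnd > 0).sum(axis=0),
                                      (w > 0).sum(axis=0))


def test_random_null_deterministic_given_seed(rng):
    w = random_weighted_graph(rng, 15, p=0.4)
    np.testing.assert_array_equal(random_null(w, seed=9), random_null(w, seed=9))


# ------------------------------------------------- small-world propensity
def test_ring_lattice_fixed_point():
    res = small_world_propensity(ring_lattice(30, 4), seed=1, n_null=10)
    assert res.delta_c <= 0.05
    assert res.delta_l >= 0.95
    assert res.phi == pytest.approx(PHI_FIXED_POINT, abs=0.03)


def test_dense_random_graph_near_random_fixed_point(rng):
    """n=30 carries visible finite-size noise in Delta_C (single observed
    realization against the null mean over a small denominator), so the
    bands here are wider than at n=100."""
    w = random_weighted_graph(rng, 30, p=0.9, lo=0.0)
    res = small_world_propensity(w, seed=2, n_null=10)
    assert res.delta_c >= 0.8
    assert res.delta_l <= 0.1
    # phi = 1 - sqrt(delta_c^2/2) drifts up to ~0.43 when delta_c dips to
    # 0.8, so the band is correspondingly wide at this size
    assert PHI_FIXED_POINT - 0.03 <= res.phi <= 0.43


def test_watts_strogatz_beats_both_fixed_points():
    w = nx.to_numpy_array(nx.watts_strogatz_graph(100, 10, 0.1, seed=3))
    res = small_world_propensity(w, seed=3, n_null=10)
    assert res.phi > PHI_FIXED_POINT + 0.1


def test_feeding_nulls_back_in_recovers_their_fixed_points(rng):
    w = random_weighted_graph(rng, 40, p=0.2)
    latt, _ = lattice_null(w)
    res_l = small_world_propensity(latt, seed=5, n_null=10)
    assert res_l.delta_c <= 0.05
    rnd = random_null(w, seed=7)
    res_r = small_world_propensity(rnd, seed=5, n_null=20)
    assert res_r.delta_l <= 0.05


def test_phi_approximately_invariant_under_node_permutation(rng):
    w = random_weighted_graph(rng, 25, p=0.3)
    perm = rng.permutation(25)
    wp = w[np.ix_(perm, perm)]
    a = small_world_propensity(w, seed=4, n_null=10)
    b = small_world_propensity(wp, seed=4, n_null=10)
    assert a.c_obs == pytest.approx(b.c_obs, abs=1e-12)
    assert a.l_obs == pytest.approx(b.l_obs, abs=1e-12)
    assert a.phi == pytest.approx(b.phi, abs=0.05)


def test_result_invariants(rng):
    w = random_weighted_graph(rng, 20, p=0.3)
    res = small_world_propensity(w, seed=6, n_null=5)
    assert 0.0 <= res.delta_c <= 1.0 and 0.0 <= res.delta_l <= 1.0
    assert res.phi == pytest.approx(
        1.0 - np.sqrt((res.delta_c ** 2 + res.delta_l ** 2) / 2.0), abs=1e-12)


def test_metrics_match_oracles_on_small_random_sweep(rng):
    for _ in range(30):
        n = int(rng.integers(4, 13))
        w = random_weighted_graph(rng, n, p=float(rng.uniform(0.2, 0.8)))
        if not w.any():
            continue
        assert weighted_clustering(w) == pytest.approx(clustering_oracle(w),
                                                       abs=1e-9)
        assert global_efficiency(w) == pytest.approx(
            global_efficiency_oracle(w), abs=1e-9)


# ------------------------------------------------------- feature records
def matrices_for(networks, rng):
    out = {}
    for name in networks:
        w = random_weighted_graph(rng, 12, p=0.6)
        w = w / max(w.max(), 1e-12)
        out[name] = ConnectivityMatrix(weights=w,
                                       node_ids=[f"n{i}" for i in range(12)],
                                       network_label=name)
    return out


def test_eight_networks_give_32_named_features(rng):
    nets = ["visual", "somatomotor", "dorsal_attention", "ventral_attention",
            "limbic", "frontoparietal", "default_mode", "whole_brain"]
    feats, complete = participant_network_features(matrices_for(nets, rng),
                                                   seed=0, n_null=3)
    assert complete
    assert len(feats) == 32
    assert all(np.isfinite(v) for v in feats.values())


def test_missing_network_flags_incomplete(rng):
    nets = ["visual", "somatomotor", "dorsal_attention", "ventral_attention",
            "limbic", "frontoparietal", "default_mode"]  # no whole brain
    feats, complete = participant_network_features(matrices_for(nets, rng),
                                                   seed=0, n_null=3)
    assert not complete
    assert len(feats) == 32
    assert np.isnan(feats["fc_whole_brain_swp"])


def test_identical_matrices_give_identical_slot_values(rng):
    w = random_weighted_graph(rng, 12, p=0.6)
    w = w / w.max()
    nets = ["visual", "somatomotor", "dorsal_attention", "ventral_attention",
            "limbic", "frontoparietal", "default_mode", "whole_brain"]
    ms = {n: ConnectivityMatrix(weights=w, node_ids=[f"n{i}" for i in range(12)],
                                network_label=n) for n in nets}
    feats, _ = participant_network_features(ms, seed=5, n_null=3)
    for metric in ("global_efficiency", "local_efficiency", "strength", "swp"):
        vals = {feats[f"fc_{n}_{metric}"] for n in nets}
        assert len(vals) == 1, metric
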