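"""Connectivity construction: correlation, Fisher-Z, thresholding, rescaling."""

import math

import numpy as np
import pytest

from brainphen.config import CohortConfig
from brainphen.connectivity import (ConnectivityMatrix, NetworkPartition,
                                    bonferroni_positive_threshold,
                                    build_connectivity, correlation_matrix,
                                    extract_subnetwork, fisher_and_standardize,
                                    rescale_weights)
from brainphen.timeseries import TimeSeriesPanel, generate_timeseries

#: Inverse upper normal tail at 5e-4 (alpha=0.05 Bonferroni over m=100),
#: frozen from a 30-digit quantile inversion: 3.29052673149189479...
Z_CRIT_5E4 = 3.2905267314918948


def panel_from(values):
    values = np.asarray(values, dtype=float)
    return TimeSeriesPanel(values=values,
                           node_ids=[f"n{i}" for i in range(values.shape[0])])


class TestCorrelation:
    def test_duplicated_and_negated_nodes(self, rng):
        x = rng.normal(size=10)
        panel = panel_from([x, x, -x, rng.normal(size=10)])
        r = correlation_matrix(panel)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_matches_covariance_formula_on_five_points(self):
        a = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # direct formula: sum of products about the means
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = math.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        r = correlation_matrix(panel_from([a, b]))
        assert r[0, 1] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_node_named(self):
        panel = panel_from([np.ones(6), np.arange(6.0)])
        with pytest.raises(ValueError, match="n0"):
            correlation_matrix(panel)


class TestFisherStandardize:
    def test_zero_r_maps_to_zero(self):
        r = np.eye(3)
        z = fisher_and_standardize(r, n=50)
        assert np.all(z == 0.0)

    @pytest.mark.parametrize("r,n,expected", [
        (0.5, 4, math.atanh(0.5)),                      # sqrt(4-3) = 1
        (0.2, 210, math.atanh(0.2) * math.sqrt(207)),   # 7-min TR-2000 run
    ])
    def test_closed_form_values(self, r, n, expected):
        mat = np.array([[1.0, r], [r, 1.0]])
        z = fisher_and_standardize(mat, n=n)
        assert z[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_perfect_correlation_rejected(self):
        mat = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="r"):
            fisher_and_standardize(mat, n=10)


class TestThreshold:
    def test_default_m_is_unique_pairs(self):
        z = np.zeros((200, 200))
        z[0, 1] = z[1, 0] = 100.0
        out = bonferroni_positive_threshold(z, alpha=0.05)
        # the survivor proves the default critical value used m = 19,900
        assert out[0, 1] == 100.0
        cm = build_connectivity(panel_from(np.random.default_rng(0)
                                           .normal(size=(10, 20))))
        assert cm.provenance["m"] == 45

    def test_all_zero_z_gives_empty_graph(self):
        out = bonferroni_positive_threshold(np.zeros((5, 5)), alpha=0.05)
        assert not out.any()

    def test_straddling_grid_matches_quantile_inversion(self):
        vals = np.array([3.0, 3.28, Z_CRIT_5E4 - 1e-9, Z_CRIT_5E4 + 1e-9,
                         3.2906, 3.5, -4.0])
        z = np.zeros((8, 8))
        z[0, 1:] = vals
        z[1:, 0] = vals
        out = bonferroni_positive_threshold(z, alpha=0.05, m=100)
        kept = out[0, 1:] > 0
        expected = vals > Z_CRIT_5E4
        np.testing.assert_array_equal(kept, expected)

    def test_threshold_monotone_in_alpha(self, rng):
        z = np.triu(rng.normal(3.5, 1.0, (30, 30)), 1)
        z = z + z.T
        prev = None
        for alpha in (0.05, 0.01, 0.001):
            kept = bonferroni_positive_threshold(z, alpha=alpha) > 0
            if prev is not None:
                assert not np.any(kept & ~prev)  # lowering alpha adds no edge
            prev = kept


class TestRescale:
    def test_single_edge_maps_to_one(self):
        z = np.zeros((3, 3))
        z[0, 1] = z[1, 0] = 7.3
        m = rescale_weights(z)
        assert m.weights[0, 1] == 1.0

    def test_max_division_dialect(self):
        z = np.zeros((3, 3))
        z[0, 1] = z[1, 0] = 2.0
        z[1, 2] = z[2, 1] = 4.0
        m = rescale_weights(z)
        assert m.weights[0, 1] == pytest.approx(0.5)
        assert m.weights[1, 2] == pytest.approx(1.0)

    def test_empty_graph_flagged(self):
        m = rescale_weights(np.zeros((4, 4)))
        assert m.empty
        assert not m.weights.any()

    def test_retained_weights_in_unit_interval(self, rng):
        z = np.triu(rng.uniform(0, 5, (20, 20)) * (rng.random((20, 20)) < 0.3), 1)
        z = z + z.T
        m = rescale_weights(z)
        w = m.weights[m.weights > 0]
        assert w.min() > 0 and w.max() == 1.0


class TestSubnetworks:
    def test_whole_brain_is_identity_restriction(self, rng):
        m = build_connectivity(panel_from(rng.normal(size=(12, 40))), alpha=0.5)
        part = NetworkPartition.contiguous(m.node_ids, 3)
        sub = extract_subnetwork(m, part, "whole_brain")
        np.testing.assert_array_equal(sub.weights, m.weights)

    def test_block_equals_brute_force_selection(self, rng):
        w = np.triu(rng.uniform(0.1, 1, (10, 10)) * (rng.random((10, 10)) < 0.6), 1)
        w = w + w.T
        ids = [f"n{i}" for i in range(10)]
        m = ConnectivityMatrix(weights=w, node_ids=ids)
        part = NetworkPartition(mapping={ids[i]: ("A" if i < 4 else "B")
                                         for i in range(10)})
        sub = extract_subnetwork(m, part, "A")
        brute = np.array([[w[i, j] for j in range(4)] for i in range(4)])
        np.testing.assert_array_equal(sub.weights, brute)
        assert sub.node_ids == ids[:4]

    def test_unknown_network_rejected(self, rng):
        m = ConnectivityMatrix(weights=np.zeros((4, 4)),
                               node_ids=list("abcd"))
        part = NetworkPartition(mapping={"a": "A", "b": "A", "c": "B", "d": "B"})
        with pytest.raises(KeyError, match="limbic"):
            extract_subnetwork(m, part, "limbic")


def test_pipeline_invariant_to_node_relabeling():
    cfg = CohortConfig(n_participants=4, n_nodes=30, n_timepoints=120, seed=3)
    panel = generate_timeseries(0.2, cfg)
    m = build_connectivity(panel)
    perm = np.random.default_rng(0).permutation(30)
    permuted = TimeSeriesPanel(values=panel.values[perm],
                               node_ids=[panel.node_ids[i] for i in perm])
    mp = build_connectivity(permuted)
    np.testing.assert_allclose(mp.weights, m.weights[np.ix_(perm, perm)],
                               atol=1e-12)


def test_end_to_end_contract():
    cfg = CohortConfig(n_participants=4, n_nodes=40, n_timepoints=210, seed=9)
    for i in range(5):
        panel = generate_timeseries(0.3, cfg, participant_index=i)
        m = build_connectivity(panel)
        w = m.weights
        np.testing.assert_array_equal(w, w.T)
        assert np.all(np.diag(w) == 0)
        assert w.min() >= 0 and w.max() <= 1.0
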