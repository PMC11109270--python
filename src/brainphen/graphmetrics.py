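"""Weighted graph metrics and small-world propensity.

Small-world propensity quantifies how closely a weighted network balances
the high clustering of a lattice against the short paths of a random
graph:

    phi = 1 - sqrt((Delta_C**2 + Delta_L**2) / 2)

with fractional deviations from degree-matched null networks

    Delta_C = (C_latt - C_obs) / (C_latt - C_rand)
    Delta_L = (L_obs - L_rand) / (L_latt - L_rand)

clipped to [0, 1]. The lattice null packs the observed edges band-by-band
around the (circular) diagonal with the largest weights at the shortest
ranges; the random null rewires edges degree-preservingly and reshuffles
the weight multiset. Both conserve node count, binary degree sequence
(best-effort for the lattice) and total weight.

Conventions: Onnela geometric-mean triangle intensity for weighted
clustering (weights normalized by the matrix maximum); shortest-path edge
length 1/w (optionally -log w); unreachable pairs are excluded from the
characteristic path length and contribute zero to global efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import random as _pyrandom

import igraph
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .config import GRAPH_METRICS, NETWORK_NAMES, WHOLE_BRAIN
from .connectivity import ConnectivityMatrix

__all__ = [
    "SWPResult", "NetworkMetricSet", "weighted_clustering",
    "characteristic_path_length", "global_efficiency", "local_efficiency",
    "mean_strength", "lattice_null", "random_null", "small_world_propensity",
    "network_metric_set", "participant_network_features",
]


def _as_weights(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def _length_matrix(w: np.ndarray, length: str) -> np.ndarray:
    lengths = np.zeros_like(w)
    mask = w > 0
    if length == "inv":
        lengths[mask] = 1.0 / w[mask]
    elif length == "neglog":
        if np.any(w[mask] > 1.0):
            raise ValueError("-log length mapping needs weights <= 1")
        lengths[mask] = -np.log(np.clip(w[mask], 1e-300, 1.0))
    else:
        raise ValueError(f"unknown length mapping {length!r}")
    return lengths


def _distances(w: np.ndarray, length: str = "inv") -> np.ndarray:
    """All-pairs shortest-path distances; inf where unreachable."""
    lengths = _length_matrix(w, length)
    return dijkstra(csr_matrix(lengths), directed=False)


def weighted_clustering(w) -> float:
    """Mean Onnela clustering coefficient.

    Per node: the mean geometric triangle intensity over the k(k-1) ordered
    neighbor pairs, with weights normalized by the matrix maximum; nodes of
    binary degree < 2 contribute 0.
    """
    w = _as_weights(w)
    if not w.any():
        return 0.0
    what = w / w.max()
    k = (w > 0).sum(axis=0)
    cube = np.cbrt(what)
    tri = np.diagonal(cube @ cube @ cube)  # 2x the triangle intensity per node
    denom = k * (k - 1)
    c = np.zeros(w.shape[0])
    ok = denom > 0
    c[ok] = tri[ok] / denom[ok]
    return float(c.mean())


def characteristic_path_length(w, length: str = "inv") -> tuple[float, bool]:
    """Mean shortest-path distance over ordered reachable pairs.

    Returns ``(L, all_reachable)``; unreachable pairs are excluded from the
    mean rather than failing, since thresholded graphs can fragment.
    A graph with no edges is rejected.
    """
    w = _as_weights(w)
    if not w.any():
        raise ValueError("characteristic path length undefined: graph has no edges")
    d = _distances(w, length)
    off = ~np.eye(w.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("no reachable pairs")
    return float(d[finite].mean()), bool(finite.sum() == off.sum())


def global_efficiency(w, length: str = "inv") -> float:
    """Mean of 1/d(i, j) over ordered pairs; unreachable pairs contribute 0."""
    w = _as_weights(w)
    n = w.shape[0]
    if n < 2 or not w.any():
        return 0.0
    d = _distances(w, length)
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & off
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].mean())


def local_efficiency(w, length: str = "inv") -> float:
    """Mean over nodes of the global efficiency of the neighborhood subgraph."""
    w = _as_weights(w)
    n = w.shape[0]
    if n == 0 or not w.any():
        return 0.0
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        eff[i] = global_efficiency(w[np.ix_(nbrs, nbrs)], length)
    return float(eff.mean())


def mean_strength(w) -> float:
    """Mean over nodes of summed incident weights."""
    w = _as_weights(w)
    if w.size == 0:
        return 0.0
    return float(w.sum(axis=0).mean())


def _ring_distance(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    d = np.abs(i - j)
    return np.minimum(d, n - d)


def lattice_null(w, seed: int = 0) -> tuple[np.ndarray, bool]:
    """Degree-matched lattice: edges packed band-by-band around the diagonal.

    Edge slots are filled at increasing circular band distance |i-j|,
    honoring each node's remaining binary degree; the observed weight
    multiset is then laid onto the slots with the largest weights at the
    smallest distances. A ring lattice is a fixed point. If the degree
    sequence cannot be packed exactly, leftover edges are placed in the
    nearest free slots and the warning flag is set. Deterministic.
    """
    w = _as_weights(w)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    edge_mask = w[iu, ju] > 0
    weights = np.sort(w[iu, ju][edge_mask])[::-1]
    n_edges = weights.size
    if n_edges == 0:
        return np.zeros_like(w), False

    degree = (w > 0).sum(axis=0).astype(int)
    band = _ring_distance(iu, ju, n)
    order = np.lexsort((ju, iu, band))  # band-by-band, then row order
    remaining = degree.copy()
    slots: list[int] = []
    skipped: list[int] = []
    for idx in order:
        if len(slots) == n_edges:
            break
        a, b = iu[idx], ju[idx]
        if remaining[a] > 0 and remaining[b] > 0:
            slots.append(idx)
            remaining[a] -= 1
            remaining[b] -= 1
        else:
            skipped.append(idx)
    warn = False
    if len(slots) < n_edges:  # degree sequence not latticizable: best effort
        warn = True
        used = set(slots)
        for idx in skipped:
            if len(slots) == n_edges:
                break
            if idx not in used:
                slots.append(idx)
    slot_arr = np.asarray(slots[:n_edges], dtype=int)
    # within the chosen slots, heaviest weights to smallest band distance
    slot_arr = slot_arr[np.argsort(band[slot_arr], kind="stable")]
    latt = np.zeros_like(w)
    latt[iu[slot_arr], ju[slot_arr]] = weights
    latt += latt.T
    return latt, warn


def random_null(w, seed: int = 0) -> np.ndarray:
    """Degree-preserving rewiring with the weight multiset reshuffled."""
    w = _as_weights(w)
    n = w.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    iu, ju = np.triu_indices(n, k=1)
    edge_mask = w[iu, ju] > 0
    weights = w[iu, ju][edge_mask]
    n_edges = weights.size
    if n_edges == 0:
        return np.zeros_like(w)

    g = igraph.Graph(n=n, edges=list(zip(iu[edge_mask].tolist(),
                                         ju[edge_mask].tolist())))
    if n_edges >= 2 and n >= 4:
        # degree-preserving double-edge swaps (Maslov-Sneppen), C-speed;
        # igraph draws from the generator installed below, so the swap
        # sequence is reproducible given the seed
        igraph.set_random_number_generator(
            _pyrandom.Random(int(rng.integers(0, 2 ** 31 - 1))))
        try:
            g.rewire(n=10 * n_edges)
        finally:
            igraph.set_random_number_generator(_pyrandom)
    rand = np.zeros_like(w)
    edges = np.array(sorted(tuple(sorted(e)) for e in g.get_edgelist()))
    perm = rng.permutation(n_edges)
    rand[edges[:, 0], edges[:, 1]] = weights[perm]
    rand += rand.T
    return rand


@dataclass
class SWPResult:
    """Small-world propensity with its constituent quantities."""

    phi: float
    delta_c: float
    delta_l: float
    c_obs: float
    c_latt: float
    c_rand: float
    l_obs: float
    l_latt: float
    l_rand: float
    clipped: dict = field(default_factory=dict)
    degenerate: dict = field(default_factory=dict)
    lattice_warning: bool = False
    all_reachable: bool = True

    def __post_init__(self) -> None:
        expected = 1.0 - np.sqrt((self.delta_c ** 2 + self.delta_l ** 2) / 2.0)
        if not np.isclose(self.phi, expected, atol=1e-12):
            raise ValueError("phi inconsistent with stored deltas")
        if not (0.0 <= self.delta_c <= 1.0 and 0.0 <= self.delta_l <= 1.0):
            raise ValueError("deltas must be stored post-clipping in [0, 1]")


def _null_ratio(num: float, den: float, key: str, result_flags: dict,
                clipped: dict) -> float:
    """(num/den) clipped to [0, 1]; degenerate null spread -> 0, flagged."""
    if abs(den) < 1e-12:
        result_flags[key] = True
        return 0.0
    ratio = num / den
    if ratio < 0.0 or ratio > 1.0:
        clipped[key] = True
    return float(np.clip(ratio, 0.0, 1.0))


def small_world_propensity(w, seed: int = 0, n_null: int = 10,
                           length: str = "inv") -> SWPResult:
    """Compute phi against lattice and random nulls.

    Random-null C and L are averaged over ``n_null`` seeded replicates;
    the lattice null is deterministic so a single realization serves as
    its average.
    """
    w = _as_weights(w)
    if not w.any():
        raise ValueError("small-world propensity undefined: graph has no edges")
    c_obs = weighted_clustering(w)
    l_obs, all_reachable = characteristic_path_length(w, length)

    latt, lattice_warning = lattice_null(w, seed)
    c_latt = weighted_clustering(latt)
    l_latt, reach_latt = characteristic_path_length(latt, length)

    c_rands, l_rands = [], []
    for rep in range(n_null):
        rnd = random_null(w, seed=seed * 100003 + rep)
        c_rands.append(weighted_clustering(rnd))
        l_rep, reach_rep = characteristic_path_length(rnd, length)
        l_rands.append(l_rep)
        all_reachable = all_reachable and reach_rep
    all_reachable = all_reachable and reach_latt
    c_rand = float(np.mean(c_rands))
    l_rand = float(np.mean(l_rands))

    degenerate: dict = {}
    clipped: dict = {}
    delta_c = _null_ratio(c_latt - c_obs, c_latt - c_rand, "delta_c",
                          degenerate, clipped)
    delta_l = _null_ratio(l_obs - l_rand, l_latt - l_rand, "delta_l",
                          degenerate, clipped)
    phi = float(1.0 - np.sqrt((delta_c ** 2 + delta_l ** 2) / 2.0))
    return SWPResult(phi=phi, delta_c=delta_c, delta_l=delta_l,
                     c_obs=c_obs, c_latt=c_latt, c_rand=c_rand,
                     l_obs=l_obs, l_latt=l_latt, l_rand=l_rand,
                     clipped=clipped, degenerate=degenerate,
                     lattice_warning=lattice_warning,
                     all_reachable=all_reachable)


@dataclass
class NetworkMetricSet:
    """The four connectivity metrics for one network slot."""

    network_label: str
    global_efficiency: float
    local_efficiency: float
    strength: float
    swp: SWPResult | None
    empty: bool = False


def network_metric_set(matrix: ConnectivityMatrix, seed: int = 0,
                       n_null: int = 10) -> NetworkMetricSet:
    w = matrix.weights
    if matrix.empty or not w.any():
        return NetworkMetricSet(network_label=matrix.network_label,
                                global_efficiency=0.0, local_efficiency=0.0,
                                strength=0.0, swp=None, empty=True)
    return NetworkMetricSet(
        network_label=matrix.network_label,
        global_efficiency=global_efficiency(w),
        local_efficiency=local_efficiency(w),
        strength=mean_strength(w),
        swp=small_world_propensity(w, seed=seed, n_null=n_null),
    )


def expected_network_slots(n_networks: int = 7) -> list[str]:
    return list(NETWORK_NAMES[:n_networks]) + [WHOLE_BRAIN]


def participant_network_features(matrices: Mapping[str, ConnectivityMatrix],
                                 seed: int = 0, n_null: int = 10,
                                 n_networks: int = 7
                                 ) -> tuple[dict[str, float], bool]:
    """4 metrics x (7 networks + whole brain) -> 32 stably named features.

    Returns ``(features, complete)``; the record is flagged incomplete when
    a network slot is missing, and absent slots yield NaN features so the
    cohort-wide column set stays stable.
    """
    slots = expected_network_slots(n_networks)
    features: dict[str, float] = {}
    complete = True
    for slot in slots:
        if slot not in matrices:
            complete = False
            for metric in GRAPH_METRICS:
                features[f"fc_{slot}_{metric}"] = float("nan")
            continue
        ms = network_metric_set(matrices[slot], seed=seed, n_null=n_null)
        features[f"fc_{slot}_global_efficiency"] = ms.global_efficiency
        features[f"fc_{slot}_local_efficiency"] = ms.local_efficiency
        features[f"fc_{slot}_strength"] = ms.strength
        features[f"fc_{slot}_swp"] = ms.swp.phi if ms.swp is not None else 0.0
    return features, complete
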