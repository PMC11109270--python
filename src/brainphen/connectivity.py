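"""Functional-connectivity construction.

Pearson correlations between node time series are Fisher Z-transformed and
variance-stabilized (multiplied by sqrt(n-3), the reciprocal of the
approximate SD sigma = 1/sqrt(n-3) for n time points), thresholded to keep
only Bonferroni-significant positive correlations (one-sided p < alpha over
the p(p-1)/2 unique node pairs), and rescaled to connection weights in
[0, 1]. Subnetwork matrices for the seven intrinsic connectivity networks
are extracted from the whole-brain thresholded matrix
(threshold-then-extract; networks are not re-thresholded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import NETWORK_NAMES, WHOLE_BRAIN
from .timeseries import TimeSeriesPanel


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative weighted adjacency with weights in [0, 1]."""

    weights: np.ndarray
    node_ids: list[str]
    network_label: str = WHOLE_BRAIN
    provenance: dict = field(default_factory=dict)
    empty: bool = False  # no edge survived thresholding

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("diagonal must be zero")
        if w.size and (w.min() < 0.0 or w.max() > 1.0 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w
        if len(self.node_ids) != w.shape[0]:
            raise ValueError("node_ids length mismatch")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def write(self, path: Path | str) -> None:
        pd.DataFrame(self.weights, index=self.node_ids,
                     columns=self.node_ids).to_csv(path, index_label="node_id")

    @classmethod
    def read(cls, path: Path | str, network_label: str = WHOLE_BRAIN) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col="node_id")
        return cls(weights=df.to_numpy(), node_ids=[str(i) for i in df.index],
                   network_label=network_label)


@dataclass
class NetworkPartition:
    """node_id -> intrinsic-network name; the whole brain is implicit."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        self.mapping = dict(self.mapping)

    @property
    def networks(self) -> list[str]:
        seen: list[str] = []
        for name in self.mapping.values():
            if name not in seen:
                seen.append(name)
        return seen

    def nodes_in(self, network: str) -> list[str]:
        if network == WHOLE_BRAIN:
            return list(self.mapping)
        if network not in set(self.mapping.values()):
            raise KeyError(f"unknown network {network!r}")
        return [n for n, net in self.mapping.items() if net == network]

    def write(self, path: Path | str) -> None:
        pd.DataFrame(
            {"node_id": list(self.mapping), "network": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: Path | str) -> "NetworkPartition":
        df = pd.read_csv(path, sep="\t")
        return cls(mapping=dict(zip(df["node_id"].astype(str), df["network"])))

    @classmethod
    def contiguous(cls, node_ids: list[str], n_networks: int = 7) -> "NetworkPartition":
        """Evenly sized contiguous blocks labelled with the canonical names."""
        names = list(NETWORK_NAMES[:n_networks])
        if len(names) < n_networks:
            names += [f"network_{i}" for i in range(len(names), n_networks)]
        bounds = np.linspace(0, len(node_ids), n_networks + 1).astype(int)
        mapping = {}
        for k in range(n_networks):
            for i in range(bounds[k], bounds[k + 1]):
                mapping[node_ids[i]] = names[k]
        return cls(mapping=mapping)


def correlation_matrix(panel: TimeSeriesPanel) -> np.ndarray:
    """Pairwise Pearson r between node time series; diagonal = 1."""
    values = panel.values
    sd = values.std(axis=1)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        names = [panel.node_ids[i] for i in dead]
        raise ValueError(f"zero-variance node(s): {names}")
    r = np.corrcoef(values)
    r = (r + r.T) / 2.0  # enforce exact symmetry over BLAS rounding
    return np.clip(r, -1.0, 1.0)


def fisher_and_standardize(r_matrix: np.ndarray, n: int) -> np.ndarray:
    """Z = arctanh(r) * sqrt(n - 3) off the diagonal; diagonal set to 0."""
    if n < 4:
        raise ValueError(f"need n >= 4 time points, got {n}")
    r = np.asarray(r_matrix, dtype=float)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        raise ValueError("|r| = 1 off-diagonal: Fisher transform is infinite")
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off]) * np.sqrt(n - 3)
    return z


def bonferroni_positive_threshold(z: np.ndarray, alpha: float = 0.05,
                                  m: int | None = None) -> np.ndarray:
    """Keep entries exceeding the one-sided critical z at level alpha/m.

    Only significant *positive* correlations survive; ``m`` defaults to the
    p(p-1)/2 unique node pairs.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    z = np.asarray(z, dtype=float)
    p = z.shape[0]
    if m is None:
        m = p * (p - 1) // 2
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    z_crit = stats.norm.isf(alpha / m)
    out = np.where(z > z_crit, z, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def rescale_weights(sparse_z: np.ndarray, node_ids: list[str] | None = None,
                    dialect: str = "max", provenance: dict | None = None
                    ) -> ConnectivityMatrix:
    """Map retained (positive) Z-scores to connection weights in [0, 1].

    ``max``: divide by the largest retained Z (zeros preserved, max -> 1).
    ``minmax``: min-max over retained edges (smallest retained edge -> 0).
    An empty graph is returned flagged, never as silent zeros.
    """
    z = np.asarray(sparse_z, dtype=float)
    if node_ids is None:
        node_ids = [f"node_{i:03d}" for i in range(z.shape[0])]
    retained = z > 0
    prov = dict(provenance or {})
    prov["rescale"] = dialect
    if not retained.any():
        return ConnectivityMatrix(weights=np.zeros_like(z), node_ids=node_ids,
                                  provenance=prov, empty=True)
    if np.any(z[z != 0.0] < 0.0):
        raise ValueError("retained entries must be positive")
    w = np.zeros_like(z)
    if dialect == "max":
        w[retained] = z[retained] / z.max()
    elif dialect == "minmax":
        lo, hi = z[retained].min(), z[retained].max()
        w[retained] = 1.0 if lo == hi else (z[retained] - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown rescale dialect {dialect!r}")
    return ConnectivityMatrix(weights=w, node_ids=node_ids, provenance=prov)


def extract_subnetwork(matrix: ConnectivityMatrix, partition: NetworkPartition,
                       name: str) -> ConnectivityMatrix:
    """Principal submatrix on one network's nodes (whole brain = identity)."""
    nodes = partition.nodes_in(name)
    index = {n: i for i, n in enumerate(matrix.node_ids)}
    missing = [n for n in nodes if n not in index]
    if missing:
        raise KeyError(f"partition nodes absent from matrix: {missing}")
    idx = np.array([index[n] for n in nodes], dtype=int)
    sub = matrix.weights[np.ix_(idx, idx)]
    return ConnectivityMatrix(weights=sub, node_ids=nodes, network_label=name,
                              provenance=dict(matrix.provenance),
                              empty=not bool((sub > 0).any()))


def build_connectivity(panel: TimeSeriesPanel, alpha: float = 0.05,
                       m: int | None = None, dialect: str = "max"
                       ) -> ConnectivityMatrix:
    """Full whole-brain route: correlate -> Fisher/standardize -> threshold -> rescale."""
    r = correlation_matrix(panel)
    z = fisher_and_standardize(r, panel.n_timepoints)
    z_thr = bonferroni_positive_threshold(z, alpha=alpha, m=m)
    p = r.shape[0]
    prov = {"alpha": alpha, "m": m if m is not None else p * (p - 1) // 2,
            "n_timepoints": panel.n_timepoints}
    return rescale_weights(z_thr, node_ids=panel.node_ids, dialect=dialect,
                           provenance=prov)
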