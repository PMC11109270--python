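"""BOLD-like time-series surrogate with controllable small-worldness.

Each participant gets a Watts-Strogatz generative graph whose rewiring
probability is set by their phenotype (delayed: near-lattice, strongly
small-world; accelerated: heavily rewired, near-random). Node signals are
drawn from a multivariate normal whose correlations decay geometrically
with graph distance, so the sample correlation matrix — and hence the
thresholded connectivity network — inherits the generative topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .config import CohortConfig, ConfigError, participant_rng

_TS_STAGE = 1  # seed fan-out slot for time-series generation


@dataclass
class TimeSeriesPanel:
    """One participant's node x time signal matrix."""

    values: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D node x time matrix")
        if self.values.shape[1] < 4:
            raise ConfigError(
                f"need >= 4 time points for sigma = 1/sqrt(n-3), got {self.values.shape[1]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in time series")
        if len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node_ids length does not match rows")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def write(self, path: Path | str) -> None:
        pd.DataFrame(self.values, index=self.node_ids).to_csv(
            path, index_label="node_id")

    @classmethod
    def read(cls, path: Path | str) -> "TimeSeriesPanel":
        df = pd.read_csv(path, index_col="node_id")
        return cls(values=df.to_numpy(), node_ids=[str(i) for i in df.index])


def target_correlation(adjacency: np.ndarray, rho: float, max_hops: int = 4,
                       min_eig: float = 1e-3) -> np.ndarray:
    """Correlation target rho**d(i,j) on a graph, projected to positive definite.

    Distances beyond ``max_hops`` (or unreachable) contribute zero
    correlation. Eigenvalues are clipped from below and the diagonal
    renormalized to 1, the nearest-PD repair standard for correlation
    targets that are not guaranteed PD on graphs with cycles.
    """
    n = adjacency.shape[0]
    if rho == 0.0 or not adjacency.any():
        return np.eye(n)
    d = shortest_path(adjacency.astype(float), method="D", unweighted=True)
    with np.errstate(invalid="ignore"):
        sigma = np.where(d <= max_hops, rho ** d, 0.0)
    sigma[~np.isfinite(d)] = 0.0
    np.fill_diagonal(sigma, 1.0)
    w, v = np.linalg.eigh(sigma)
    if w.min() < min_eig:
        w = np.clip(w, min_eig, None)
        sigma = (v * w) @ v.T
        scale = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(scale, scale)
        np.fill_diagonal(sigma, 1.0)
    return sigma


def generate_timeseries(rewire_prob: float, config: CohortConfig,
                        participant_index: int = 0) -> TimeSeriesPanel:
    """Simulate one participant's node x time panel.

    ``rewire_prob`` is the Watts-Strogatz beta from the participant's
    planted truth; lower values yield more lattice-like (higher
    small-world-propensity) correlation structure.
    """
    config.validate()
    if config.n_timepoints <= 3:
        raise ConfigError(
            f"n_timepoints must be >= 4 for sigma = 1/sqrt(n-3), got {config.n_timepoints}")
    if config.n_nodes < 4:
        raise ConfigError(f"n_nodes must be >= 4, got {config.n_nodes}")
    rng = participant_rng(config.seed, _TS_STAGE, participant_index)
    graph_seed = int(rng.integers(0, 2 ** 31 - 1))
    k = min(config.ws_k, config.n_nodes - 1)
    g = nx.watts_strogatz_graph(config.n_nodes, k, rewire_prob, seed=graph_seed)
    adjacency = nx.to_numpy_array(g, nodelist=range(config.n_nodes))

    sigma = target_correlation(adjacency, config.edge_rho)
    chol = np.linalg.cholesky(sigma)
    values = chol @ rng.standard_normal((config.n_nodes, config.n_timepoints))
    node_ids = [f"node_{i:03d}" for i in range(config.n_nodes)]
    return TimeSeriesPanel(values=values, node_ids=node_ids)
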