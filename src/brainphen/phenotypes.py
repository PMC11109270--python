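"""Phenotype discovery by hierarchical clustering of brain features.

Participants are clustered on their prepared brain-domain features
(structure, metabolism, connectivity — cognition and nutrients are held
out so downstream comparisons are not circular) with complete linkage on
Euclidean distances, cut into two clusters at the final merge, and the
clusters oriented: "delayed" aging is the cluster with the higher mean
over the structural (volume + DTI) columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree

from .cohort import ACCELERATED, DELAYED
from .prep import PreparedMatrix

BRAIN_CLUSTER_DOMAINS = ("structure.volume", "structure.dti", "metabolism",
                         "connectivity")
ORIENTATION_DOMAINS = ("structure.volume", "structure.dti")


@dataclass
class LinkageTree:
    """Merge sequence of an agglomerative clustering."""

    merges: np.ndarray             # scipy linkage matrix, (n-1) x 4
    participant_ids: list[str]
    metric: str = "euclidean"
    method: str = "complete"

    def __post_init__(self) -> None:
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be nondecreasing")

    @property
    def n(self) -> int:
        return len(self.participant_ids)

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        root = to_tree(self.merges)

        def fmt(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.participant_ids[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({fmt(root.left, root.dist)},{fmt(root.right, root.dist)});" \
            if not root.is_leaf() else f"({self.participant_ids[root.id]});"

    def write(self, newick_path: Path | str, merges_csv: Path | str) -> None:
        Path(newick_path).write_text(self.to_newick() + "\n")
        pd.DataFrame(self.merges,
                     columns=["left", "right", "height", "size"]).to_csv(
            merges_csv, index=False)


@dataclass
class PhenotypeAssignment:
    """participant -> accelerated | delayed, with the orientation record."""

    labels: pd.Series
    orientation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = self.labels.value_counts()
        if set(counts.index) != {ACCELERATED, DELAYED} or (counts < 1).any():
            raise ValueError("need exactly two nonempty phenotype groups")

    def members(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]

    def write(self, path: Path | str) -> None:
        self.labels.rename("phenotype").to_csv(path, index_label="participant_id")


def cluster_participants(matrix: PreparedMatrix,
                         domains: tuple[str, ...] = BRAIN_CLUSTER_DOMAINS,
                         method: str = "complete",
                         metric: str = "euclidean") -> LinkageTree:
    """Complete-linkage tree on Euclidean distances between participants."""
    cols = sorted(matrix.features(*domains))  # column-order invariance
    X = matrix.values[cols].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    if np.isnan(X).any():
        raise ValueError("NaN in prepared matrix")
    Z = linkage(X, method=method, metric=metric)
    return LinkageTree(merges=Z, participant_ids=list(matrix.values.index),
                       metric=metric, method=method)


def cut_two(tree: LinkageTree) -> pd.Series:
    """The two clusters obtained by removing the final merge.

    Returns unoriented integer labels (1 / 2) indexed by participant.
    """
    flat = fcluster(tree.merges, t=2, criterion="maxclust")
    return pd.Series(flat, index=pd.Index(tree.participant_ids,
                                          name="participant_id"),
                     name="cluster")


def orient_labels(clusters: pd.Series, matrix: PreparedMatrix,
                  domains: tuple[str, ...] = ORIENTATION_DOMAINS
                  ) -> PhenotypeAssignment:
    """Name the cluster with higher structural integrity "delayed".

    The composite is the mean of the prepared volume and DTI columns. Exact
    ties break on group size (larger group = delayed), then on which group
    holds the lexicographically smallest participant id; the applied rule
    is recorded.
    """
    groups = sorted(clusters.unique())
    if len(groups) != 2:
        raise ValueError(f"expected 2 clusters, got {len(groups)}")
    cols = matrix.features(*domains)
    composite = matrix.values[cols].mean(axis=1)
    means = {g: float(composite[clusters == g].mean()) for g in groups}
    rule = {"composite_domains": list(domains), "group_means": means}
    a, b = groups
    if means[a] != means[b]:
        delayed_group = a if means[a] > means[b] else b
        rule["tie_break"] = None
    else:
        sizes = {g: int((clusters == g).sum()) for g in groups}
        if sizes[a] != sizes[b]:
            delayed_group = a if sizes[a] > sizes[b] else b
            rule["tie_break"] = "group_size"
        else:
            first = clusters.index.min()
            delayed_group = clusters.loc[first]
            rule["tie_break"] = "lowest_participant_id"
    labels = clusters.map(lambda g: DELAYED if g == delayed_group else ACCELERATED)
    labels.name = "phenotype"
    return PhenotypeAssignment(labels=labels, orientation=rule)


def discover_phenotypes(matrix: PreparedMatrix,
                        domains: tuple[str, ...] = BRAIN_CLUSTER_DOMAINS,
                        method: str = "complete", metric: str = "euclidean"
                        ) -> tuple[LinkageTree, PhenotypeAssignment]:
    tree = cluster_participants(matrix, domains=domains, method=method,
                                metric=metric)
    return tree, orient_labels(cut_two(tree), matrix)


#: Rows of the domain summary: (domain label, measure family, column filter).
_SUMMARY_ROWS = (
    ("Brain Structure", "Volumetric Regions",
     lambda m: m.features("structure.volume")),
    ("Brain Structure", "Diffusion Tensor Imaging Tracts",
     lambda m: m.features("structure.dti")),
    ("Brain Metabolism", "Magnetic Resonance Spectroscopy",
     lambda m: m.features("metabolism")),
    ("Functional Connectivity", "Whole Brain",
     lambda m: [c for c in m.features("connectivity")
                if c.startswith("fc_whole_brain_")]),
    ("Functional Connectivity", "Small World Propensity (network)",
     lambda m: [c for c in m.features("connectivity")
                if c.endswith("_swp") and not c.startswith("fc_whole_brain_")]),
    ("Functional Connectivity", "Strength (network)",
     lambda m: [c for c in m.features("connectivity")
                if c.endswith("_strength") and not c.startswith("fc_whole_brain_")]),
    ("Functional Connectivity", "Local efficiency (network)",
     lambda m: [c for c in m.features("connectivity")
                if c.endswith("_local_efficiency")
                and not c.startswith("fc_whole_brain_")]),
    ("Functional Connectivity", "Global efficiency (network)",
     lambda m: [c for c in m.features("connectivity")
                if c.endswith("_global_efficiency")
                and not c.startswith("fc_whole_brain_")]),
)


def domain_summaries(assignment: PhenotypeAssignment,
                     matrix: PreparedMatrix) -> pd.DataFrame:
    """Per-domain, per-phenotype means of the scaled values.

    Mirrors the layout of the group-mean summary table: one row per
    (domain, measure family), columns for the accelerated and delayed
    means. Empty measure families are omitted with a warning.
    """
    import warnings

    rows = []
    acc = assignment.members(ACCELERATED)
    dly = assignment.members(DELAYED)
    for domain, measure, pick in _SUMMARY_ROWS:
        cols = pick(matrix)
        if not cols:
            warnings.warn(f"no columns for summary row {measure!r}; omitted")
            continue
        block = matrix.values[cols]
        rows.append({
            "domain": domain, "measure": measure,
            "accelerated": float(block.loc[acc].to_numpy().mean()),
            "delayed": float(block.loc[dly].to_numpy().mean()),
        })
    return pd.DataFrame(rows)
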