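"""Phenotype contrasts: per-feature t-tests, brain age, nutrient profile.

Two-group comparisons use the Welch (unequal-variance) t-test by default,
two-sided, unadjusted at alpha = 0.05 — a Benjamini-Hochberg column is
always emitted alongside for transparency. The brain-age report contrasts
raw BA (in years) between phenotypes and correlates BA with per-modality
composites (unweighted means of the prepared columns in each domain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ACCELERATED, DELAYED, CohortTable
from .config import NUTRIENT_PANEL_DEFAULT
from .phenotypes import PhenotypeAssignment
from .prep import PreparedMatrix

#: Modality composites correlated with brain age.
MODALITY_DOMAINS = {
    "volumes": ("structure.volume",),
    "tracts": ("structure.dti",),
    "metabolites": ("metabolism",),
    "connectivity": ("connectivity",),
}


def two_group_t(x_a, x_b, welch: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test of the means; Welch variant by default."""
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.size < 2 or x_b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x_a) == 0.0 and np.var(x_b) == 0.0:
        if np.mean(x_a) == np.mean(x_b):
            return 0.0, 1.0
        raise ValueError("degenerate zero variance in both groups")
    res = stats.ttest_ind(x_a, x_b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def compare_all(matrix: PreparedMatrix, assignment: PhenotypeAssignment,
                domains: tuple[str, ...], alpha: float = 0.05,
                welch: bool = True) -> pd.DataFrame:
    """One comparison record per feature in the requested domains.

    Columns: feature, domain, mean_accelerated, mean_delayed, t_statistic,
    p_value, significant (unadjusted at alpha), p_bh (Benjamini-Hochberg),
    significant_bh. Sorted by domain then p-value.
    """
    if not domains:
        raise ValueError("empty domain selection")
    cols = matrix.features(*domains)
    if not cols:
        raise ValueError(f"no features found in domains {domains}")
    acc = assignment.members(ACCELERATED)
    dly = assignment.members(DELAYED)
    dom_map = dict(zip(matrix.manifest["feature"], matrix.manifest["domain"]))
    records = []
    for col in cols:
        xa = matrix.values.loc[acc, col].to_numpy()
        xd = matrix.values.loc[dly, col].to_numpy()
        t, p = two_group_t(xa, xd, welch=welch)
        records.append({
            "feature": col, "domain": dom_map[col],
            "mean_accelerated": float(xa.mean()),
            "mean_delayed": float(xd.mean()),
            "t_statistic": t, "p_value": p,
            "significant": bool(p < alpha),
        })
    out = pd.DataFrame(records)
    _, p_bh, _, _ = multipletests(out["p_value"], alpha=alpha, method="fdr_bh")
    out["p_bh"] = p_bh
    out["significant_bh"] = out["p_bh"] < alpha
    return out.sort_values(["domain", "p_value"], kind="stable").reset_index(drop=True)


@dataclass
class BrainAgeReport:
    mean_accelerated: float
    mean_delayed: float
    difference: float            # accelerated minus delayed, in years
    t_statistic: float
    p_value: float
    modality_correlations: pd.DataFrame  # modality, r, p (or degenerate flag)
    degenerate: bool = False

    def __post_init__(self) -> None:
        expected = self.mean_accelerated - self.mean_delayed
        if not np.isclose(self.difference, expected, atol=1e-12):
            raise ValueError("difference must equal mean_accelerated - mean_delayed")


def brain_age_report(cohort: CohortTable, assignment: PhenotypeAssignment,
                     matrix: PreparedMatrix, welch: bool = True
                     ) -> BrainAgeReport:
    """Brain-age contrast in years plus BA-modality Pearson correlations."""
    if "brain_age" not in cohort.data.columns:
        raise ValueError("cohort has no brain_age column")
    ba = cohort.data["brain_age"]
    acc = assignment.members(ACCELERATED)
    dly = assignment.members(DELAYED)
    degenerate = float(ba.std(ddof=0)) == 0.0
    if degenerate:
        t, p = float("nan"), float("nan")
    else:
        t, p = two_group_t(ba.loc[acc], ba.loc[dly], welch=welch)

    direction = dict(zip(matrix.manifest["feature"], matrix.manifest["direction"]))
    rows = []
    for modality, domains in MODALITY_DOMAINS.items():
        cols = matrix.features(*domains)
        if not cols:
            continue
        # align reverse-scored columns (1 - x on the [0,1] scale) so the
        # composite indexes modality health in a single direction
        block = matrix.values[cols].copy()
        for c in cols:
            if direction.get(c) == "reverse":
                block[c] = 1.0 - block[c]
        composite = block.mean(axis=1)
        if degenerate or composite.std(ddof=0) == 0.0:
            rows.append({"modality": modality, "r": float("nan"),
                         "p": float("nan"), "degenerate": True})
            continue
        r, rp = stats.pearsonr(ba.loc[composite.index], composite)
        rows.append({"modality": modality, "r": float(r), "p": float(rp),
                     "degenerate": False})
    mean_acc = float(ba.loc[acc].mean())
    mean_dly = float(ba.loc[dly].mean())
    return BrainAgeReport(
        mean_accelerated=mean_acc, mean_delayed=mean_dly,
        difference=mean_acc - mean_dly, t_statistic=t, p_value=p,
        modality_correlations=pd.DataFrame(rows), degenerate=degenerate)


def nutrient_profile(records: pd.DataFrame,
                     categories: dict | None = None) -> pd.DataFrame:
    """Nutrients significantly higher in the delayed phenotype.

    From a ``compare_all`` table: keeps nutrient-domain records that are
    significant at the unadjusted level with delayed mean > accelerated
    mean, annotated with the panel's category labels. May be empty.
    """
    if categories is None:
        categories = {k: v[0] for k, v in NUTRIENT_PANEL_DEFAULT.items()}
    nut = records[records["domain"] == "nutrient"]
    keep = nut[nut["significant"] & (nut["mean_delayed"] > nut["mean_accelerated"])]
    out = keep.copy()
    out.insert(0, "category", [categories.get(f, "Other") for f in out["feature"]])
    return out.sort_values(["category", "feature"]).reset_index(drop=True)
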