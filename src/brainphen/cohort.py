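"""Synthetic cohort with planted two-phenotype structure.

Generates a participant x feature table covering every modality the
downstream pipeline consumes — volumetrics, DTI fractional anisotropy,
MRS metabolites, functional-connectivity graph metrics, cognitive scores,
nutrient biomarkers, covariates, and brain age — with a known
accelerated/delayed group assignment and per-feature planted effects, so
phenotype recovery can be tested against ground truth.

Every feature is Gaussian with within-group SD 1: value = mu_g + b'c + e,
where mu_g = +/- d/2 by group, c are standardized covariates explaining a
configurable variance share (covariates are independent of group, so they
can never explain the phenotypes), and e is white noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    COGNITIVE_TESTS,
    CONNECTIVITY_METRIC_SIGN,
    COVARIATES,
    GRAPH_METRICS,
    METABOLITES,
    NETWORK_NAMES,
    STRUCTURAL_REGIONS,
    WHOLE_BRAIN,
    CohortConfig,
    ConfigError,
    stage_rng,
)

ACCELERATED = "accelerated"
DELAYED = "delayed"

BRAIN_DOMAINS = ("structure.volume", "structure.dti", "metabolism", "connectivity")


@dataclass
class CohortTable:
    """Participants x named features with domain tags.

    ``data`` is indexed by participant_id; ``manifest`` has one row per
    feature column with its domain tag and scoring direction
    ("higher_is_better" or "reverse").
    """

    data: pd.DataFrame
    manifest: pd.DataFrame  # columns: feature, domain, direction

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate participant ids")
        tagged = set(self.manifest["feature"])
        untagged = [c for c in self.data.columns if c not in tagged]
        if untagged:
            raise ValueError(f"untagged feature columns: {untagged}")

    def features(self, *domains: str) -> list[str]:
        """Feature names belonging to any of the given domain tags."""
        mask = self.manifest["domain"].isin(domains)
        return [f for f in self.manifest.loc[mask, "feature"] if f in self.data.columns]

    @property
    def covariate_columns(self) -> list[str]:
        return self.features("covariate")

    def write(self, cohort_csv: Path | str, manifest_csv: Path | str) -> None:
        self.data.to_csv(cohort_csv, index_label="participant_id")
        self.manifest.to_csv(manifest_csv, index=False)

    @classmethod
    def read(cls, cohort_csv: Path | str, manifest_csv: Path | str) -> "CohortTable":
        data = pd.read_csv(cohort_csv, index_col="participant_id")
        manifest = pd.read_csv(manifest_csv)
        return cls(data=data, manifest=manifest)


@dataclass
class PlantedTruth:
    """Ground truth behind a synthetic cohort, for recovery tests."""

    labels: pd.Series                 # participant_id -> accelerated|delayed
    effects: pd.DataFrame             # feature, domain, planted_d (signed, delayed-minus-accelerated)
    rewire_prob: pd.Series = field(default=None)  # participant_id -> WS rewiring p

    def __post_init__(self) -> None:
        values = set(self.labels.unique())
        if not values <= {ACCELERATED, DELAYED}:
            raise ValueError(f"unexpected labels: {values}")


def feature_names(config: CohortConfig) -> pd.DataFrame:
    """Feature manifest (name, domain, direction) implied by a config.

    Canonical anatomical/test names are used when counts match the default
    study layout; otherwise names are generated (`vol_000`, ...), keeping
    counts fully configurable.
    """
    rows: list[tuple[str, str, str]] = []

    if config.n_volumes == 2 * len(STRUCTURAL_REGIONS):
        vol = [f"vol_{r}_{h}" for r in STRUCTURAL_REGIONS for h in ("lh", "rh")]
    else:
        vol = [f"vol_{i:03d}" for i in range(config.n_volumes)]
    rows += [(f, "structure.volume", "higher_is_better") for f in vol]

    if config.n_tracts == len(STRUCTURAL_REGIONS):
        fa = [f"fa_{r}" for r in STRUCTURAL_REGIONS]
    else:
        fa = [f"fa_{i:03d}" for i in range(config.n_tracts)]
    rows += [(f, "structure.dti", "higher_is_better") for f in fa]

    if config.n_metabolites == len(METABOLITES):
        met = [f"mrs_{m}" for m in METABOLITES]
    else:
        met = [f"mrs_{i:02d}" for i in range(config.n_metabolites)]
    rows += [(f, "metabolism", "higher_is_better") for f in met]

    for net in list(NETWORK_NAMES[: config.n_networks]) + [WHOLE_BRAIN]:
        for metric in GRAPH_METRICS:
            # network-level strength/efficiency run opposite to brain health
            # in this cohort design; the manifest records that so composites
            # can align features before averaging
            sign = 1.0 if net == WHOLE_BRAIN else CONNECTIVITY_METRIC_SIGN[metric]
            direction = "higher_is_better" if sign > 0 else "reverse"
            rows.append((f"fc_{net}_{metric}", "connectivity", direction))

    if config.n_cognitive == len(COGNITIVE_TESTS):
        cog = list(COGNITIVE_TESTS)
    else:
        cog = [f"cog_{i:02d}" for i in range(config.n_cognitive)]
    for f in cog:
        direction = "reverse" if f in config.reverse_scored else "higher_is_better"
        rows.append((f, "cognition", direction))

    for nut in config.nutrient_panel:
        rows.append((nut, "nutrient", "higher_is_better"))

    rows += [(c, "covariate", "higher_is_better") for c in COVARIATES]
    rows.append(("brain_age", "brain_age", "reverse"))  # lower BA = younger brain

    return pd.DataFrame(rows, columns=["feature", "domain", "direction"])


def planted_effects(config: CohortConfig, manifest: pd.DataFrame) -> pd.DataFrame:
    """Signed per-feature effect (delayed minus accelerated, SD units)."""
    d_brain = dict(config.effect_size_brain)
    records = []
    for _, row in manifest.iterrows():
        f, dom = row["feature"], row["domain"]
        if dom in ("structure.volume", "structure.dti", "metabolism"):
            d = d_brain.get(dom, 0.0)
        elif dom == "connectivity":
            metric = next(m for m in GRAPH_METRICS if f.endswith(m))
            base = d_brain.get("connectivity", 0.0)
            sign = 1.0 if f.startswith(f"fc_{WHOLE_BRAIN}_") \
                else CONNECTIVITY_METRIC_SIGN[metric]
            d = sign * base
        elif dom == "cognition":
            d = config.effect_size_cognition
            if row["direction"] == "reverse":
                d = -d  # delayed group is faster / makes fewer errors
        elif dom == "nutrient":
            d = config.nutrient_panel[f][1]
        else:  # covariates and brain_age handled separately
            d = 0.0
        records.append((f, dom, d))
    return pd.DataFrame(records, columns=["feature", "domain", "planted_d"])


def _covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Demographics for a healthy elderly cohort, independent of phenotype."""
    return pd.DataFrame({
        "age": rng.normal(70.0, 4.5, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "education": rng.normal(16.0, 2.5, n),
        "income": rng.normal(6.0, 2.0, n),
        "bmi": rng.normal(27.0, 4.0, n),
    })


def generate_cohort(config: CohortConfig) -> tuple[CohortTable, PlantedTruth]:
    """Draw a cohort with planted two-phenotype structure.

    Identical config + seed gives byte-identical output. Covariate loadings
    per feature are drawn once (seeded) and scaled so covariates explain
    ``covariate_r2`` of each feature's within-group variance, leaving the
    within-group SD exactly 1 so planted d is the realized standardized
    mean difference.
    """
    config.validate()
    if config.n_timepoints <= 3:
        raise ConfigError(
            f"n_timepoints must be >= 4 for sigma = 1/sqrt(n-3), got {config.n_timepoints}")
    rng = stage_rng(config.seed, 0)
    n = config.n_participants

    n_delayed = int(round(n * config.group_fraction))
    n_delayed = min(max(n_delayed, 1), n - 1)
    labels = np.array([DELAYED] * n_delayed + [ACCELERATED] * (n - n_delayed))
    rng.shuffle(labels)
    group_sign = np.where(labels == DELAYED, 1.0, -1.0)

    manifest = feature_names(config)
    effects = planted_effects(config, manifest)
    d_map = dict(zip(effects["feature"], effects["planted_d"]))

    cov = _covariates(n, rng)
    cov_std = (cov - cov.mean()) / cov.std(ddof=0).replace(0.0, 1.0)
    C = cov_std.to_numpy()

    data = {}
    r2 = config.covariate_r2
    for _, row in manifest.iterrows():
        f, dom = row["feature"], row["domain"]
        if dom == "covariate":
            continue
        if dom == "brain_age":
            mu_acc, mu_del = config.brain_age_means
            mu = np.where(labels == DELAYED, mu_del, mu_acc)
            data[f] = mu + rng.normal(0.0, config.brain_age_sd, n)
            continue
        beta = rng.normal(0.0, 1.0, C.shape[1])
        if r2 > 0:
            beta *= np.sqrt(r2 / np.sum(beta ** 2))
        else:
            beta[:] = 0.0
        noise = rng.normal(0.0, np.sqrt(1.0 - r2), n)
        data[f] = 0.5 * d_map[f] * group_sign + C @ beta + noise

    table = pd.DataFrame(data)
    for c in COVARIATES:
        table[c] = cov[c].to_numpy()
    table.index = pd.Index([f"sub-{i:03d}" for i in range(n)], name="participant_id")
    # column order follows the manifest
    table = table[[f for f in manifest["feature"]]]

    rewire = pd.Series(
        np.where(labels == DELAYED, config.rewire_delayed, config.rewire_accelerated),
        index=table.index, name="rewire_prob")
    truth = PlantedTruth(
        labels=pd.Series(labels, index=table.index, name="group"),
        effects=effects,
        rewire_prob=rewire,
    )
    return CohortTable(data=table, manifest=manifest), truth
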