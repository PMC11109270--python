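"""Configuration objects for the synthetic cohort and the pipeline.

The cohort configuration encodes the study conditions the generator
emulates: a healthy elderly cohort of ~100 adults with 68 volumetric
measures, 34 white-matter tracts, 3 MRS metabolites, 32 functional
connectivity metrics (4 graph metrics x 7 networks + whole brain),
15 cognitive scores (two reverse-scored), a ~30-nutrient blood biomarker
panel of which 13 differ between phenotypes, five covariates, and a
per-participant brain age with a group gap of 5.4 years.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

#: Desikan-Killiany cortical regions measured for both volume (x2 hemispheres)
#: and white-matter integrity.
STRUCTURAL_REGIONS: tuple[str, ...] = (
    "banks_superior_temporal", "caudal_anterior_cingulate",
    "caudal_middle_frontal", "cuneus", "entorhinal", "frontal_pole",
    "fusiform", "inferior_parietal", "inferior_temporal", "insula",
    "isthmus_cingulate", "lateral_occipital", "lateral_orbitofrontal",
    "lingual", "medial_orbitofrontal", "middle_temporal", "paracentral",
    "parahippocampal", "pars_opercularis", "pars_orbitalis",
    "pars_triangularis", "pericalcarine", "postcentral",
    "posterior_cingulate", "precentral", "precuneus",
    "rostral_anterior_cingulate", "rostral_middle_frontal",
    "superior_frontal", "superior_parietal", "superior_temporal",
    "supramarginal", "temporal_pole", "transverse_temporal",
)

METABOLITES: tuple[str, ...] = ("naa", "choline", "creatine")

#: The seven intrinsic connectivity networks, plus the implicit whole brain.
NETWORK_NAMES: tuple[str, ...] = (
    "visual", "somatomotor", "dorsal_attention", "ventral_attention",
    "limbic", "frontoparietal", "default_mode",
)
WHOLE_BRAIN = "whole_brain"

GRAPH_METRICS: tuple[str, ...] = (
    "global_efficiency", "local_efficiency", "swp", "strength",
)

COGNITIVE_TESTS: tuple[str, ...] = (
    "wasi_fsiq4", "wasi_pri", "wasi_vci", "wasi_block_design",
    "wasi_matrix_reasoning",
    "dkefs_trails_1", "dkefs_trails_2", "dkefs_trails_3", "dkefs_trails_4",
    "dkefs_trails_5", "dkefs_trails_errors",
    "wms_ami", "wms_vmi", "wms_imi", "wms_dmi",
)

#: Reaction time and error counts: lower is better.
REVERSE_SCORED_DEFAULT: tuple[str, ...] = ("dkefs_trails_5", "dkefs_trails_errors")

#: Blood nutrient biomarkers: name -> (category, planted effect size d).
#: The 13 nutrients characterizing the delayed phenotype get d = 0.8;
#: the remaining panel members are null.
NUTRIENT_PANEL_DEFAULT: dict[str, tuple[str, float]] = {
    # Differing nutrients
    "c18_1n7_vaccenic": ("Fatty Acids", 0.8),
    "c20_1n9_gondoic": ("Fatty Acids", 0.8),
    "c18_3n3_ala": ("Fatty Acids", 0.8),
    "c20_5n3_epa": ("Fatty Acids", 0.8),
    "c22_2n6_docosadienoic": ("Fatty Acids", 0.8),
    "c20_2n6_eicosadienoic": ("Fatty Acids", 0.8),
    "c24_0_lignoceric": ("Fatty Acids", 0.8),
    "cis_lutein": ("Antioxidants and Carotenoids", 0.8),
    "trans_lutein": ("Antioxidants and Carotenoids", 0.8),
    "zeaxanthin": ("Antioxidants and Carotenoids", 0.8),
    "alpha_tocopherol": ("Vitamins and Vitamin-Like Compounds", 0.8),
    "gamma_tocopherol": ("Vitamins and Vitamin-Like Compounds", 0.8),
    "choline": ("Vitamins and Vitamin-Like Compounds", 0.8),
    # Null nutrients
    "vitamin_a": ("Vitamins and Vitamin-Like Compounds", 0.0),
    "vitamin_b2": ("Vitamins and Vitamin-Like Compounds", 0.0),
    "vitamin_b6": ("Vitamins and Vitamin-Like Compounds", 0.0),
    "vitamin_b12": ("Vitamins and Vitamin-Like Compounds", 0.0),
    "vitamin_d": ("Vitamins and Vitamin-Like Compounds", 0.0),
    "lycopene": ("Antioxidants and Carotenoids", 0.0),
    "carotene": ("Antioxidants and Carotenoids", 0.0),
    "c10_0_capric": ("Fatty Acids", 0.0),
    "c12_0_lauric": ("Fatty Acids", 0.0),
    "c14_0_myristic": ("Fatty Acids", 0.0),
    "c16_0_palmitic": ("Fatty Acids", 0.0),
    "c18_0_stearic": ("Fatty Acids", 0.0),
    "c20_0_arachidic": ("Fatty Acids", 0.0),
    "c22_0_behenic": ("Fatty Acids", 0.0),
    "c18_4n3_stearidonic": ("Fatty Acids", 0.0),
    "c22_4n6_adrenic": ("Fatty Acids", 0.0),
}

COVARIATES: tuple[str, ...] = ("age", "sex", "education", "income", "bmi")

#: Per-metric sign of the planted delayed-minus-accelerated difference for
#: network-level connectivity features: the delayed phenotype is higher on
#: small-world propensity but lower on strength and efficiencies, while all
#: whole-brain metrics favor the delayed group.
CONNECTIVITY_METRIC_SIGN: dict[str, float] = {
    "swp": +1.0,
    "strength": -1.0,
    "local_efficiency": -1.0,
    "global_efficiency": -1.0,
}


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort generator.

    Effect sizes are standardized mean differences (delayed minus
    accelerated, within-group SD = 1) in the "good" direction for each
    domain; signs per feature are applied internally (reverse-scored
    cognition negated, connectivity per :data:`CONNECTIVITY_METRIC_SIGN`).
    """

    n_participants: int = 100
    group_fraction: float = 0.5          # fraction in the delayed group
    n_volumes: int = 68
    n_tracts: int = 34
    n_metabolites: int = 3
    n_nodes: int = 200
    n_networks: int = 7                  # plus whole brain
    n_timepoints: int = 210              # 7 min at TR = 2000 ms
    n_cognitive: int = 15
    reverse_scored: tuple[str, ...] = REVERSE_SCORED_DEFAULT
    nutrient_panel: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(NUTRIENT_PANEL_DEFAULT))
    effect_size_brain: Mapping[str, float] = field(default_factory=lambda: {
        "structure.volume": 1.0,
        "structure.dti": 1.0,
        "metabolism": 1.0,
        "connectivity": 1.0,
    })
    effect_size_cognition: float = 0.5
    brain_age_means: tuple[float, float] = (65.1, 59.7)  # (accelerated, delayed)
    brain_age_sd: float = 10.0
    covariate_r2: float = 0.2            # variance share explained by covariates
    # Time-series surrogate parameters (Watts-Strogatz generative graphs)
    ws_k: int = 10
    rewire_delayed: float = 0.1
    rewire_accelerated: float = 0.8
    edge_rho: float = 0.5                # target correlation on planted edges
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_participants": self.n_participants, "n_volumes": self.n_volumes,
            "n_tracts": self.n_tracts, "n_metabolites": self.n_metabolites,
            "n_nodes": self.n_nodes, "n_networks": self.n_networks,
            "n_timepoints": self.n_timepoints, "n_cognitive": self.n_cognitive,
        }
        for name, value in counts.items():
            if not (isinstance(value, (int, np.integer)) and value >= 1):
                raise ConfigError(f"{name} must be an integer >= 1, got {value!r}")
        if not (0.0 < self.group_fraction < 1.0):
            raise ConfigError(
                f"group_fraction must be in (0, 1), got {self.group_fraction!r}")
        for dom, d in self.effect_size_brain.items():
            if not math.isfinite(d):
                raise ConfigError(f"effect_size_brain[{dom!r}] is not finite: {d!r}")
        if not math.isfinite(self.effect_size_cognition):
            raise ConfigError(
                f"effect_size_cognition is not finite: {self.effect_size_cognition!r}")
        for nut, (_, d) in self.nutrient_panel.items():
            if not math.isfinite(d):
                raise ConfigError(f"nutrient_panel[{nut!r}] effect is not finite: {d!r}")
        for fld in ("brain_age_sd", "covariate_r2", "edge_rho",
                    "rewire_delayed", "rewire_accelerated"):
            v = getattr(self, fld)
            if not math.isfinite(v):
                raise ConfigError(f"{fld} is not finite: {v!r}")
        if not all(math.isfinite(m) for m in self.brain_age_means):
            raise ConfigError(f"brain_age_means not finite: {self.brain_age_means!r}")
        if not (0.0 <= self.covariate_r2 < 1.0):
            raise ConfigError(f"covariate_r2 must be in [0, 1), got {self.covariate_r2!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["nutrient_panel"] = {k: list(v) for k, v in self.nutrient_panel.items()}
        d["reverse_scored"] = list(self.reverse_scored)
        d["brain_age_means"] = list(self.brain_age_means)
        d["effect_size_brain"] = dict(self.effect_size_brain)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "nutrient_panel" in d:
            d["nutrient_panel"] = {k: tuple(v) for k, v in d["nutrient_panel"].items()}
        if "reverse_scored" in d:
            d["reverse_scored"] = tuple(d["reverse_scored"])
        if "brain_age_means" in d:
            d["brain_age_means"] = tuple(d["brain_age_means"])
        return cls(**d)


@dataclass
class RunConfig:
    """One reproducible pipeline run: cohort conditions + analysis knobs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    alpha: float = 0.05
    n_null_reps: int = 10                # null-model replicates for SWP
    linkage_method: str = "complete"
    distance_metric: str = "euclidean"
    welch: bool = True
    connectivity_from_timeseries: bool = False
    seed: int = 0
    out_dir: str = "runs/default"

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha!r}")
        if self.n_null_reps < 1:
            raise ConfigError(f"n_null_reps must be >= 1, got {self.n_null_reps!r}")
        self.cohort.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Derive an independent generator for a pipeline stage.

    A counter-based fan-out from the single global seed, so each stage is
    reproducible in isolation.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(int(stage),)))


def participant_rng(seed: int, stage: int, participant: int) -> np.random.Generator:
    """Per-participant generator nested under a stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(int(stage), int(participant))))
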