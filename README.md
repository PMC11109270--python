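# brainphen

Multimodal brain-health phenotyping: from functional-connectivity
networks and small-world propensity to data-driven discovery of
*accelerated* vs *delayed* brain-aging phenotypes and their cognitive and
nutritional correlates.

## The problem

Healthy elderly adults differ widely in how their brains age. Given a
participant × feature table spanning brain structure (regional volumes,
white-matter tract FA), metabolism (MRS metabolite concentrations),
function (graph metrics of fMRI connectivity networks), cognition,
blood nutrient biomarkers, and a per-participant *brain age* (BA, a
structural-MRI-predicted age), this package:

1. builds weighted functional-connectivity networks per participant and
   scores them with graph metrics, including **small-world propensity**;
2. prepares every outcome column: covariate residualization
   (Frisch–Waugh–Lovell), Tukey's Ladder of Powers toward normality,
   then [0, 1] scaling;
3. clusters participants on their brain features with complete-linkage
   hierarchical clustering and cuts two phenotypes, oriented so
   "delayed" is the cluster with higher structural integrity;
4. contrasts the phenotypes with two-sample t-tests: brain age (in
   years), cognition, and the nutrient biomarker panel.

Because cohort data of this kind is shareable only on request, the
package ships a synthetic cohort generator with *planted* two-phenotype
structure across all modalities, so every stage is testable against
ground truth.

## The core statistic

For a weighted network with clustering coefficient C_obs and
characteristic path length L_obs, small-world propensity is

    Φ = 1 − sqrt((Δ_C² + Δ_L²) / 2)

    Δ_C = (C_latt − C_obs) / (C_latt − C_rand)
    Δ_L = (L_obs − L_rand) / (L_latt − L_rand)

where C_latt, L_latt come from a degree-matched **lattice null** (edges
packed band-by-band around the diagonal, heaviest weights at the
shortest ranges) and C_rand, L_rand from a degree-preserving **random
null** (edge rewiring with the weight multiset reshuffled), both
conserving node count, binary degrees and total weight. Δ ratios are
clipped to [0, 1]; a ring lattice and a dense random graph both sit at
Φ = 1 − √½ ≈ 0.293, and genuinely small-world topologies score higher.

Connectivity matrices feeding Φ are built from node time series by
Pearson correlation, Fisher Z-transform standardized by √(n−3) for n
time points, a Bonferroni-corrected one-sided threshold keeping only
significant positive correlations, and rescaling of retained Z-scores
to weights in [0, 1].

## Worked example

The numbered scripts under `analysis/` run the study on the default
synthetic cohort (n = 100, 137 brain features, planted effects):

```
$ python analysis/05_compare_phenotypes.py
brain age: accelerated 65.3 y vs delayed 59.0 y; gap 6.2 y (t = 2.98, p = 0.00364)

BA-modality correlations:
    modality      r     p  degenerate
     volumes -0.260 0.009       False
      tracts -0.257 0.010       False
 metabolites -0.210 0.036       False
connectivity -0.271 0.006       False

significant cognitive contrasts: 11 of 15
```

The two clusters found from brain features alone split the cohort 50/50
(adjusted Rand index 1.0 against the planted labels); the accelerated
phenotype carries a ~6-year brain-age excess, all four modality
composites correlate negatively with BA, and the nutrient profile of the
delayed phenotype recovers the 13 planted biomarkers (fatty acids,
lutein/zeaxanthin, tocopherols, choline). `analysis/02` shows the
time-series route: panels generated from near-lattice topologies yield
mean Φ ≈ 0.64 versus ≈ 0.43 for heavily rewired ones.

There is also a CLI (`brainphen simulate | connectivity | metrics |
prepare | phenotype | compare | all`) wrapping the same library calls,
e.g. `brainphen all --seed 1 --out runs/demo`.

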