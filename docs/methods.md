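# Methods

This note documents the models, parameter choices, numerical decisions
and limitations behind `brainphen`. Nothing here states a result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic cohort: what it emulates

The generator (`brainphen.cohort`) emulates a healthy elderly cohort
(default n = 100) with two latent brain-health phenotypes, *accelerated*
and *delayed* aging, at a configurable mixing fraction (default 0.5).
Feature layout follows the study design it models:

- 68 regional volumes (34 cortical regions × 2 hemispheres),
- 34 white-matter tract FA values,
- 3 MRS metabolites (NAA, choline, creatine),
- 32 functional-connectivity metrics (4 graph metrics × 7 intrinsic
  networks + whole brain),
- 15 cognitive scores, two of them reverse-scored (a trails reaction
  time and an error count, where lower is better),
- 29 blood nutrient biomarkers, 13 with a planted group difference
  (vaccenic, gondoic, ALA, EPA, docosadienoic, eicosadienoic and
  lignoceric acids; cis-/trans-lutein and zeaxanthin; α- and
  γ-tocopherol; choline) and 16 null (vitamins A/B2/B6/B12/D, lycopene,
  carotene, even-chain saturates C10:0–C22:0, stearidonic and adrenic
  acids),
- covariates age, sex, education, income, BMI,
- per-participant brain age.

The brain-feature total (68+34+32+3 = 137) is always derived from the
configured counts, never hard-coded.

Every feature is Gaussian with within-group SD 1:
`x = ±d/2 + β·c + ε`, where d is the planted standardized mean
difference (delayed minus accelerated, positive in the feature's
"good" direction), c are the standardized covariates and the loadings β
are drawn once per feature (seeded) and scaled so covariates explain a
fixed variance share (default R² = 0.2), leaving the realized
within-group SD exactly 1. Covariates are drawn independently of the
phenotype, so by construction they can never explain it — the
pipeline's covariate check should, and does, come out null.

Gaussian noise everywhere is deliberate: the preparation stage
Tukey-transforms toward normality anyway, and Gaussian features keep
the planted-effect recovery tests analytic (a planted d is the realized
standardized mean difference, recoverable within 3 standard errors).

Default effect sizes: d = 1.0 per brain feature (two cleanly separable
phenotypes at 137 features), d = 0.5 for cognition, d = 0.8 for the 13
differing nutrients. Brain-age group means default to (65.1, 59.7)
years with SD 10; at a 50/50 split of n = 100 that SD implies a Welch t
of about 5.4/(10·√(2/50)) ≈ 2.7 for the 5.4-year gap, i.e. a gap that
is significant but not overwhelming — the regime the design targets.

Connectivity features carry a per-metric sign pattern: small-world
propensity and all whole-brain metrics favor the delayed phenotype,
while network-level strength and local/global efficiency favor the
accelerated phenotype. The feature manifest records the reversed ones
as `reverse`-scored.

### Time-series surrogate

`brainphen.timeseries` generates node × time panels (default 200 nodes,
210 time points ≈ 7 min at TR 2 s) whose correlation structure follows
a per-participant Watts–Strogatz graph: rewiring probability 0.1 for
delayed (strongly small-world) and 0.8 for accelerated (near-random) —
the canonical WS regimes. The target correlation decays as
ρ^(graph distance) with ρ = 0.5 on planted edges, chosen so true edges
clear the Bonferroni r-threshold (~0.31 at n = 210 over 19,900 pairs)
while two-step correlations (~0.25) mostly do not. The target matrix is
repaired to positive definite by eigenvalue clipping (floor 1e-3) with
the diagonal renormalized, then sampled through its Cholesky factor.

What this surrogate does *not* emulate: hemodynamics, autocorrelated
BOLD noise, motion artifacts, negative correlations structure, or any
spatial embedding of the parcellation. Passing tests therefore show
that the connectivity/SWP machinery recovers planted topology
differences from finite noisy samples — not that real BOLD data would
behave this way.

## Connectivity construction

Pearson correlations are Fisher Z-transformed and multiplied by
√(n−3) — the reciprocal of the approximate SD 1/√(n−3) of arctanh(r) —
to give standard normal scores under the null. A one-sided Bonferroni
threshold at α = 0.05 over m = p(p−1)/2 unique pairs keeps only
significant *positive* correlations; negative correlations are
discarded. Retained Z-scores are divided by the within-matrix maximum,
so weights lie in (0, 1] with zeros preserved (a min–max dialect over
retained edges is available). Subnetworks (7 intrinsic networks) are
extracted from the whole-brain thresholded matrix — threshold-then-
extract, not per-network re-thresholding — so subnetwork weights remain
comparable. A matrix with no surviving edge is returned flagged, never
as silent zeros.

## Graph metrics and small-world propensity

- **Clustering**: Onnela geometric-mean triangle intensity, weights
  normalized by the matrix maximum; nodes of binary degree < 2
  contribute 0. Chosen because the weighted small-world-propensity
  literature uses it; the normalization makes Δ_C invariant to uniform
  weight rescaling.
- **Path length**: shortest paths on edge lengths 1/w (−log w is
  available); the characteristic path length averages over ordered
  *reachable* pairs and flags fragmentation rather than failing, since
  Bonferroni-thresholded graphs can fragment. Global efficiency counts
  unreachable pairs as 0; local efficiency is the mean over nodes of
  the global efficiency of the neighborhood subgraph; strength is the
  mean node-summed weight.
- **Lattice null**: edge slots are filled at increasing circular band
  distance |i−j| subject to each node's remaining binary degree, and
  the observed weight multiset is laid on with the heaviest weights at
  the shortest ranges. A ring lattice is an exact fixed point. When a
  degree sequence cannot be packed exactly, leftover edges go to the
  nearest free slots and a warning flag is set.
- **Random null**: degree-preserving double-edge swaps (10 per edge,
  C-level implementation) followed by a uniform reshuffle of the weight
  multiset; deterministic given the seed.
- **Φ**: Δ_C = (C_latt−C_obs)/(C_latt−C_rand) and
  Δ_L = (L_obs−L_rand)/(L_latt−L_rand), each clipped to [0, 1] (clipping
  flagged); a near-zero denominator (null spread below 1e−12) defines
  the ratio as 0 with a flag. Random-null C and L are averaged over a
  configurable number of seeded replicates (default 10); the lattice
  null is deterministic, so one realization is its average.

**Fixed-point conditioning.** The two reference points Φ = 1 − √½ are
exact only in expectation. For a single observed random graph, Δ_C
deviates from 1 by (C_obs − E C_rand)/(C_latt − C_rand); at n = 30 this
denominator is small enough that Φ wanders up to ~0.1 above the fixed
point, while at n = 100 the property is tight (observed within ~0.01).
Tests assert the n = 30 case with correspondingly wide bands and the
sharp bands at n = 100.

## Feature preparation

Each outcome column (brain, cognition, nutrient alike) is

1. **residualized** on [1, age, sex, education, income, BMI] by least
   squares — the Frisch–Waugh–Lovell partialling-out; categorical
   covariates expand to indicator columns; a rank-deficient design is
   rejected naming the collinear columns;
2. **Tukey-transformed**: λ from a grid (−2 to 2, step 0.025) maximizing
   the Shapiro–Wilk W of the transformed column, with the transform
   x^λ (λ>0), log x (λ=0), −x^λ (λ<0) applied after shifting the signed
   residuals to strictly positive support (shift = −min + 10⁻⁶·range).
   All rungs are monotone increasing, so ranks are preserved exactly.
   The grid is scanned coarse-to-fine (every 0.2, then full resolution
   within ±0.2 of the coarse optimum); W is smooth in λ, and the
   refinement reproduces the flat scan's λ on every column type tested,
   at a quarter of the cost. Ties resolve toward λ = 1;
3. **min–max scaled** to [0, 1]; constant columns are rejected, not
   silently centered.

Brain age is *not* prepared — it is reported in years. Missing values
are rejected (the generator never produces them; real tables should be
handled upstream). Per-column lineage (λ, shift, scaling bounds,
covariates) is recorded and replayable.

## Phenotype discovery

Complete-linkage hierarchical clustering on Euclidean distances between
participants' prepared *brain-domain* columns only (structure,
metabolism, connectivity). Cognition and nutrients are held out of the
clustering: they are the downstream outcomes, and including them would
make the phenotype contrasts circular. Columns are sorted before
distance computation, so the tree is invariant to column order; merge
heights are checked nondecreasing (complete linkage guarantees it).

Two phenotypes come from removing the final merge (k = 2); the cut
height is not data-tuned because the design targets exactly two groups.
Orientation: the cluster with the higher mean over prepared volume +
DTI columns is *delayed*; exact ties break on group size, then on the
lexicographically smallest participant id, and the applied rule is
recorded in the assignment.

The pipeline flags the cut as non-separated when the two-cluster
silhouette on the brain columns falls below 0.05. The threshold was set
by a pilot contrast of the generator's regimes: all-null cohorts score
≤ ~0.03 and default planted cohorts ~0.19–0.21, so 0.05 splits the two
with wide margins.

## Group comparisons

Welch (unequal-variance) t-tests by default — the pooled variant is
selectable — two-sided, reported unadjusted at α = 0.05, with a
Benjamini–Hochberg column always emitted alongside. The brain-age
report gives group means, the difference in years and its t-test, plus
Pearson correlations between BA and per-modality composites. A
composite is the unweighted mean of the prepared columns in a domain
*after aligning reverse-scored columns* (x → 1−x on the [0, 1] scale):
without alignment, the 21 connectivity columns that favor the
accelerated phenotype would dominate the connectivity composite and
flip its sign, making the composite an index of nothing in particular.
The nutrient profile lists nutrient-domain records significant at α
with the delayed mean above the accelerated mean.

## Pipeline and reproducibility

`run_pipeline` executes simulate → (optional time-series connectivity
recompute) → prepare → phenotype → compare, writing every artifact with
a SHA-256 content hash into a run manifest; identical config + seed
gives identical hashes. The single run seed fans out to stage- and
participant-level generators through `numpy.random.SeedSequence` spawn
keys, so stages are independently reproducible.

By default the cohort's connectivity columns are the planted Gaussian
features. The generative time-series route cannot reproduce the planted
sign pattern end to end — in a Watts–Strogatz world, local efficiency
tracks clustering and would favor the *delayed* group, the opposite of
the design's network-level reversal — so the directions are planted,
and the time-series → connectivity → Φ route is validated separately
(its planted topology difference must and does survive the full
thresholding pipeline). Setting `connectivity_from_timeseries` replaces
the 32 connectivity columns with metrics computed from simulated
panels.

## Problem sizes used in tests and acceptance

The test suite runs cohorts at the default n = 100 with 20-seed sweeps
for recovery and power, 10,000 replicates for t-test calibration,
200 random graphs (≤ 12 nodes) against brute-force oracles, and
50 synthetic panels (40 nodes) for the connectivity contract; the
time-series SWP contrast uses 60-node panels at the full 210 time
points. These sizes are the package's own choices for tight, analytic
ground truth at desk scale.

## Known limitations

- The lattice null's greedy band packing is best-effort for irregular
  degree sequences (flagged); it does not search for the optimal
  latticization.
- Φ is only approximately invariant to node permutation (the band
  packing and the rewiring trajectory depend on labeling); tests bound
  the wobble at 0.05.
- The silhouette-based separation flag is a heuristic calibrated on the
  generator's regimes, not a hypothesis test for cluster number.
- Real-data features the generator omits: missing values, outliers
  beyond what the Tukey step normalizes, non-Gaussian biomarker
  distributions, covariate–phenotype confounding, site/batch effects.
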