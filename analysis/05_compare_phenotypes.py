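#!/usr/bin/env python
"""Contrast the discovered phenotypes: brain age, cognition, nutrients.

Writes results/brain_age_contrast.csv, results/cognition_comparisons.csv
and results/nutrient_profile.csv, and prints the headline contrast.
"""

from pathlib import Path

import pandas as pd

from brainphen.cohort import generate_cohort
from brainphen.compare import brain_age_report, compare_all, nutrient_profile
from brainphen.config import CohortConfig
from brainphen.phenotypes import discover_phenotypes
from brainphen.prep import prepare

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort, _ = generate_cohort(CohortConfig(seed=1))
    prepped = prepare(cohort)
    _, assignment = discover_phenotypes(prepped)

    records = compare_all(prepped, assignment,
                          domains=("cognition", "nutrient"))
    ba = brain_age_report(cohort, assignment, prepped)
    profile = nutrient_profile(records)

    OUT.mkdir(exist_ok=True)
    records[records["domain"] == "cognition"].to_csv(
        OUT / "cognition_comparisons.csv", index=False)
    profile.to_csv(OUT / "nutrient_profile.csv", index=False)
    ba_rows = [{"quantity": "mean_BA_accelerated", "value": ba.mean_accelerated},
               {"quantity": "mean_BA_delayed", "value": ba.mean_delayed},
               {"quantity": "difference_years", "value": ba.difference},
               {"quantity": "t_statistic", "value": ba.t_statistic},
               {"quantity": "p_value", "value": ba.p_value}]
    pd.DataFrame(ba_rows).to_csv(OUT / "brain_age_contrast.csv", index=False)

    print(f"brain age: accelerated {ba.mean_accelerated:.1f} y vs delayed "
          f"{ba.mean_delayed:.1f} y; gap {ba.difference:.1f} y "
          f"(t = {ba.t_statistic:.2f}, p = {ba.p_value:.3g})")
    print("\nBA-modality correlations:")
    print(ba.modality_correlations.round(3).to_string(index=False))
    n_sig_cog = int(records[records["domain"] == "cognition"]["significant"].sum())
    print(f"\nsignificant cognitive contrasts: {n_sig_cog} of "
          f"{(records['domain'] == 'cognition').sum()}")
    print(f"nutrients higher in the delayed phenotype: {len(profile)}")
    print(profile[["category", "feature", "p_value"]].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
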