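#!/usr/bin/env python
"""Generate the synthetic study cohort and CT/MRI validation pairs.

Writes the full subject-level tables (large) under scratch/ and a compact
demographic summary under results/.  Later analysis steps regenerate the
same tables in memory from the master seed, so this script is for
inspection, not a dependency.
"""

from pathlib import Path

import pandas as pd

from braintrends.io import ensure_dir
from braintrends.regions import load_region_registry
from braintrends.synthetic import SynthConfig, generate_cohort, generate_validation_pairs

MASTER_SEED = 7

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    registry = load_region_registry()
    config = SynthConfig(seed=MASTER_SEED)
    cohort = generate_cohort(config, registry)
    pairs = generate_validation_pairs(config, 13, registry)

    scratch = ensure_dir(ROOT / "scratch" / "synthetic")
    cohort.to_csv(scratch / "cohort.csv", index=False)
    pairs.to_csv(scratch / "validation_pairs.csv", index=False)

    summary = (
        cohort.groupby(["population", "sex"])
        .agg(n=("subject_id", "size"), age_mean=("age", "mean"),
             age_sd=("age", "std"), icv_mean=("icv", "mean"))
        .round(2)
        .reset_index()
    )
    results = ensure_dir(ROOT / "results")
    summary.to_csv(results / "cohort_demographics.tsv", sep="\t", index=False)
    print(f"cohort: {len(cohort)} subjects across {summary.shape[0]} groups")
    print(summary.to_string(index=False))
    print(f"validation pairs: {pairs['subject_id'].nunique()} subjects x 148 regions")


if __name__ == "__main__":
    main()
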