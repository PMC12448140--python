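#!/usr/bin/env python
"""Pairwise Fisher scans of the E18.5 features against looping class and
trajectory group, BH-adjusted and ordered by p-value.

Writes results/associations_<focal>.csv and a Sankey flow export for the top
association of each scan.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from looptrax.cohort_io import default_schema, filter_analysis_set, read_cohort
from looptrax.stats import pairwise_scan, sankey_flows
from looptrax.trajectory import with_trajectory_groups

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

schema = default_schema()
cohort = with_trajectory_groups(read_cohort(args.data / "cohort.csv", schema))
cohort, excluded = filter_analysis_set(cohort, "classify")
print(f"{len(cohort)} individuals retained, {len(excluded)} excluded")

features = list(schema.analysis_set("classify").variables)
args.out.mkdir(parents=True, exist_ok=True)
for focal in ("looping_class", "trajectory_group"):
    feats = [f for f in features if f != "ventricle_laterality"] \
        if focal == "trajectory_group" else features
    results = pairwise_scan(cohort, focal, feats, seed=args.seed)
    pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "n_used": [r.n_used for r in results],
            "method": [r.test.method for r in results],
        }
    ).to_csv(args.out / f"associations_{focal}.csv", index=False)
    top = results[0]
    (args.out / f"sankey_{focal}_{top.feature}.json").write_text(
        json.dumps(sankey_flows(top.table), indent=1)
    )
    print(f"focal={focal}: top association {top.feature} "
          f"(p={top.p_raw:.2e}, adjusted={top.p_adjusted:.2e}, n={top.n_used})")
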