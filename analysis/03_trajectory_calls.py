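#!/usr/bin/env python
"""Call congruent/revertant trajectories between E9.5 looping and E18.5 laterality.

Reads results/data/cohort.csv, cross-tabulates looping direction against
final ventricle laterality, and reports the revertant fractions (overall and
per looping direction).  Writes results/trajectory_table.csv and the Sankey
flow list results/trajectory_flows.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from looptrax.cohort_io import default_schema, read_cohort
from looptrax.trajectory import trajectory_table

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cohort = read_cohort(args.data / "cohort.csv", default_schema())
table = trajectory_table(cohort)

args.out.mkdir(parents=True, exist_ok=True)
pd.DataFrame(table.counts, index=table.row_labels, columns=table.col_labels).to_csv(
    args.out / "trajectory_table.csv"
)
(args.out / "trajectory_flows.json").write_text(json.dumps(table.flows, indent=1))

print(f"{table.n_classified} classified, {table.n_unclassified} unclassified")
print(f"revertant fraction: {table.revertant_fraction:.1%}")
print(f"revertant among leftward loopers:  {table.revertant_among_leftward:.1%}")
print(f"revertant among rightward loopers: {table.revertant_among_rightward:.1%}")
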