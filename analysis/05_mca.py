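#!/usr/bin/env python
"""Multiple correspondence analysis of the 11-variable E18.5 feature set.

Excludes records with uncertain diagnoses (the MCA analysis set), fits the
indicator-matrix MCA, and writes eigenvalues, individual coordinates, level
contributions, v-tests, and the scatter export colored by looping class and
by trajectory group.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from looptrax.cohort_io import default_schema, filter_analysis_set, read_cohort
from looptrax.mca import mca_fit, mca_project_plot_data
from looptrax.trajectory import with_trajectory_groups

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results/mca"))
parser.add_argument("--dims", type=int, default=5)
args = parser.parse_args()

schema = default_schema()
cohort = with_trajectory_groups(read_cohort(args.data / "cohort.csv", schema))
mca_cohort, excluded = filter_analysis_set(cohort, "mca")
print(f"{len(mca_cohort)} individuals in the MCA ({len(excluded)} excluded):")
for e in excluded:
    print(f"  - {e['subject_id']}: {e['variable']} = {e['value']}")

res = mca_fit(mca_cohort, schema.analysis_set("mca").variables, n_dims=args.dims)
args.out.mkdir(parents=True, exist_ok=True)
pd.Series(res.eigenvalues, name="eigenvalue").to_csv(args.out / "eigenvalues.csv")
res.row_coords.to_csv(args.out / "row_coords.csv")
res.col_coords.to_csv(args.out / "level_coords.csv")
res.contributions.to_csv(args.out / "contributions.csv")
res.v_tests.to_csv(args.out / "v_tests.csv")
for color in ("looping_class", "trajectory_group"):
    mca_project_plot_data(res, mca_cohort, color).to_csv(args.out / f"scatter_{color}.csv")

strong = res.v_tests[res.v_tests.abs() > 2].stack().dropna()
print(f"total inertia {res.total_inertia:.3f} over {res.J - res.Q} dimensions; "
      f"dim1 explains {res.explained_inertia[0]:.1%}")
print(f"{len(strong)} level/dimension pairs with |v| > 2 (strong associations)")
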