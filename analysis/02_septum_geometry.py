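#!/usr/bin/env python
"""Quantify ventricle position from the septum landmarks and classify cases.

Reads results/data/landmarks.json, projects each subject's interventricular-
septum normal onto its anatomical frame, builds the central 99% reference
interval from the controls, and calls each case normal / superoinferior /
strictly left-right.  Writes results/orientations.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from looptrax.geometry import (
    classify_orientation,
    control_interval,
    landmarks_from_json,
    orientation_from_landmarks,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--coverage", type=float, default=0.99)
args = parser.parse_args()

landmarks = landmarks_from_json(json.loads((args.data / "landmarks.json").read_text()))
orientations = [orientation_from_landmarks(lm) for lm in landmarks]
ref = control_interval(
    [o for o, lm in zip(orientations, landmarks) if lm.group == "control"],
    coverage=args.coverage,
)

rows = []
for o, lm in zip(orientations, landmarks):
    cat = "control" if lm.group == "control" else classify_orientation(o, ref)
    rows.append({"subject_id": o.subject_id, "group": lm.group,
                 "c_cc": o.c_cc, "c_dv": o.c_dv, "c_lr": o.c_lr, "category": cat})
df = pd.DataFrame(rows)
args.out.mkdir(parents=True, exist_ok=True)
df.to_csv(args.out / "orientations.csv", index=False)

case_counts = df.loc[df.group != "control", "category"].value_counts()
print(f"reference interval from {ref.n_controls} controls at {args.coverage:.0%} coverage")
print("case calls:", case_counts.to_dict())
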