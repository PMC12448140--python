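"""Looping-direction semantics, congruent/revertant calling, and stage kinetics.

At E9.5 the embryonic heart tube loops rightward (classes 2 and 4) or
leftward (classes 1 and 3).  The clinical nomenclature expects rightward
looping to give a D-LOOP at E18.5 (anatomic right ventricle on the right)
and leftward looping an L-LOOP; an individual whose final laterality is
discordant with its looping direction is a *revertant* — evidence that
ventricle position remains plastic after looping.  The stage-kinetics
operation quantifies when the population proportion of rightward
configurations shifts, by pooling stages into two epochs around a split
point and comparing them with a chi-square test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats as sps

from .cohort_io import Cohort, CohortSchema, PhenotypeRecord, VariableSchema

__all__ = [
    "CONGRUENT_LATERALITY",
    "TrajectoryCall",
    "StageProportion",
    "direction_of_class",
    "call_trajectory",
    "trajectory_table",
    "TrajectoryTable",
    "with_trajectory_groups",
    "stage_kinetics",
    "KineticsResult",
]

Direction = Literal["rightward", "leftward", "unknown"]
Group = Literal["rightward_congruent", "leftward_congruent", "revertant", "unclassified"]

#: laterality expected from each looping direction under the congruence postulate
CONGRUENT_LATERALITY = {"rightward": "D", "leftward": "L"}

STAGE_ORDER = ("E9.5", "E10.5", "E12.5", "E13.5", "E14.5", "E18.5")


def direction_of_class(looping_class: int | str) -> Direction:
    """Looping direction of a class: 2 and 4 loop rightward, 1 and 3 leftward."""
    c = str(looping_class)
    if c in {"2", "4"}:
        return "rightward"
    if c in {"1", "3"}:
        return "leftward"
    return "unknown"


def call_trajectory(direction: str, laterality: str) -> Group:
    """Congruent/revertant call from looping direction and final laterality.

    (rightward, D) and (leftward, L) are congruent; the two mismatches are
    revertant; any unknown input leaves the individual unclassified.
    """
    if direction not in CONGRUENT_LATERALITY or laterality not in {"D", "L"}:
        return "unclassified"
    if CONGRUENT_LATERALITY[direction] == laterality:
        return "rightward_congruent" if direction == "rightward" else "leftward_congruent"
    return "revertant"


@dataclass(frozen=True)
class TrajectoryCall:
    subject_id: str
    direction_e9: Direction
    laterality_e18: str
    group: Group


@dataclass(frozen=True)
class TrajectoryTable:
    """2x2 direction-by-laterality counts with the headline fractions."""

    counts: np.ndarray  # rows (rightward, leftward) x cols (D, L)
    calls: tuple[TrajectoryCall, ...]
    n_classified: int
    n_unclassified: int
    revertant_fraction: float
    revertant_among_leftward: float
    revertant_among_rightward: float

    row_labels = ("rightward", "leftward")
    col_labels = ("D", "L")

    @property
    def flows(self) -> list[dict]:
        """Sankey flows (source looping direction -> target laterality)."""
        out = []
        for i, src in enumerate(self.row_labels):
            for j, tgt in enumerate(self.col_labels):
                if self.counts[i, j] > 0:
                    out.append({"source": src, "target": tgt, "count": int(self.counts[i, j])})
        return out


def trajectory_table(cohort: Cohort) -> TrajectoryTable:
    """Cross-tabulate looping direction against final ventricle laterality.

    Individuals with an unknown looping class or laterality are excluded
    from every fraction denominator and reported separately.
    """
    counts = np.zeros((2, 2), dtype=int)
    calls = []
    unclassified = 0
    for rec in cohort.records:
        direction = direction_of_class(rec.looping_class)
        laterality = rec.features.get("ventricle_laterality", "unknown")
        group = call_trajectory(direction, laterality)
        calls.append(
            TrajectoryCall(
                subject_id=rec.subject_id,
                direction_e9=direction,
                laterality_e18=laterality,
                group=group,
            )
        )
        if group == "unclassified":
            unclassified += 1
            continue
        i = 0 if direction == "rightward" else 1
        j = 0 if laterality == "D" else 1
        counts[i, j] += 1

    n = int(counts.sum())
    n_right, n_left = counts[0].sum(), counts[1].sum()
    revertant = counts[0, 1] + counts[1, 0]  # rightward->L and leftward->D
    return TrajectoryTable(
        counts=counts,
        calls=tuple(calls),
        n_classified=n,
        n_unclassified=unclassified,
        revertant_fraction=revertant / n if n else math.nan,
        revertant_among_leftward=counts[1, 0] / n_left if n_left else math.nan,
        revertant_among_rightward=counts[0, 1] / n_right if n_right else math.nan,
    )


def with_trajectory_groups(cohort: Cohort) -> Cohort:
    """Return a cohort extended with a derived ``trajectory_group`` variable.

    The new outcome variable carries the congruent/revertant call per
    individual (missing code ``unclassified``), so downstream scans and
    classifiers can treat it like any schema variable.
    """
    group_var = VariableSchema(
        name="trajectory_group",
        role="outcome",
        levels=("rightward_congruent", "leftward_congruent", "revertant"),
        missing_codes=("unclassified",),
    )
    schema = CohortSchema(
        variables=(*cohort.schema.variables, group_var),
        analysis_sets=cohort.schema.analysis_sets,
    )
    records = tuple(
        PhenotypeRecord(
            subject_id=r.subject_id,
            uterine_position=r.uterine_position,
            genotype=r.genotype,
            looping_class=r.looping_class,
            features={
                **r.features,
                "trajectory_group": call_trajectory(
                    direction_of_class(r.looping_class),
                    r.features.get("ventricle_laterality", "unknown"),
                ),
            },
        )
        for r in cohort.records
    )
    return Cohort(records=records, schema=schema, provenance=cohort.provenance)


# ---------------------------------------------------------------------------
# stage kinetics


@dataclass(frozen=True)
class StageProportion:
    stage: str
    n: int
    k_rightward: int
    proportion: float
    standard_error: float


@dataclass(frozen=True)
class KineticsResult:
    stages: tuple[StageProportion, ...]
    early_proportion: float
    early_se: float
    early_n: int
    late_proportion: float
    late_se: float
    late_n: int
    chi2: float
    p_value: float
    epoch_split: str


def _proportion(stage: str, n: int, k: int) -> StageProportion:
    if n <= 0:
        raise ValueError(f"stage {stage!r}: zero count")
    if not 0 <= k <= n:
        raise ValueError(f"stage {stage!r}: k_rightward outside [0, n]")
    p = k / n
    return StageProportion(
        stage=stage, n=n, k_rightward=k, proportion=p,
        standard_error=math.sqrt(p * (1 - p) / n),
    )


def stage_kinetics(
    stage_records: Sequence[tuple[str, int, int]],
    epoch_split: str = "E13.5",
    stage_order: Sequence[str] = STAGE_ORDER,
) -> KineticsResult:
    """Per-stage rightward proportions and the two-epoch shift test.

    ``stage_records`` holds (stage label, n, k_rightward) triples.  Stages
    strictly before ``epoch_split`` (in developmental order) form the early
    epoch, the rest the late epoch; pooled counts are compared with a
    Pearson chi-square test on the 2x2 epoch-by-configuration table (no
    continuity correction).  The default split between E12.5 and E13.5 is
    the remodeling window of the study system.
    """
    order = {s: i for i, s in enumerate(stage_order)}
    if epoch_split not in order:
        raise ValueError(f"epoch_split {epoch_split!r} not in stage order {list(stage_order)}")
    stages = tuple(_proportion(s, n, k) for s, n, k in stage_records)
    early = [s for s in stages if order[s.stage] < order[epoch_split]]
    late = [s for s in stages if order[s.stage] >= order[epoch_split]]
    if not early or not late:
        raise ValueError("each epoch needs at least one stage")

    def pool(group: Iterable[StageProportion]) -> tuple[int, int]:
        ns = [(s.n, s.k_rightward) for s in group]
        return sum(n for n, _ in ns), sum(k for _, k in ns)

    n_e, k_e = pool(early)
    n_l, k_l = pool(late)
    table = np.array([[k_e, n_e - k_e], [k_l, n_l - k_l]])
    if (table.sum(axis=0) == 0).any():
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    p_e, p_l = k_e / n_e, k_l / n_l
    return KineticsResult(
        stages=stages,
        early_proportion=p_e,
        early_se=math.sqrt(p_e * (1 - p_e) / n_e),
        early_n=n_e,
        late_proportion=p_l,
        late_se=math.sqrt(p_l * (1 - p_l) / n_l),
        late_n=n_l,
        chi2=float(chi2),
        p_value=float(p),
        epoch_split=epoch_split,
    )
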