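"""Seeded generators for synthetic cohorts, landmark sets, and survival records.

The generators reproduce the statistical structure the downstream analyses
assume, so the whole pipeline is exercisable without any real data:

* a categorical cohort whose individuals draw an embryonic looping class
  (classes 2 and 4 loop rightward, 1 and 3 leftward), flip their final
  ventricle laterality with a direction-specific reversion probability, and
  then draw the E18.5 anatomical parameters from trajectory-conditional
  tables;
* noisy 3D landmark sets scattered around group-specific septum
  orientations in a common template frame;
* two-group exponential survival with independent exponential censoring and
  an administrative horizon.

Defaults mirror the cohort-scale figures of the study system: a 45/55
leftward/rightward looping split, reversion probabilities 11/18 after
leftward and 1/22 after rightward looping, and sparse missingness in the
variables that drive sample exclusion.  The conditional E18.5 feature tables
are illustrative (the real association strengths are a property of the data,
not published as tables); users can supply tables estimated from a real
cohort.  All generators are pure functions of (model, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort_io import Cohort, CohortSchema, PhenotypeRecord, default_schema
from .geometry import LandmarkSet, build_frame, plane_normal
from .survival import SurvivalRecord
from .trajectory import CONGRUENT_LATERALITY, call_trajectory, direction_of_class

__all__ = [
    "CohortModel",
    "LandmarkModel",
    "SurvivalModel",
    "simulate_cohort",
    "simulate_landmarks",
    "simulate_survival",
    "spawn_seeds",
    "default_feature_tables",
]

TRAJECTORY_GROUPS = ("rightward_congruent", "leftward_congruent", "revertant")


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan one master seed out into ``n`` independent sub-stream seeds (< 2^31).

    Adding a stream at the end never perturbs earlier streams.
    """
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


# ---------------------------------------------------------------------------
# categorical cohort


def default_feature_tables() -> dict[str, dict[str, dict[str, float]]]:
    """Illustrative trajectory-conditional E18.5 feature distributions.

    Keyed variable -> trajectory group -> level -> probability.  The planted
    structure follows the biology of the study system: revertants are
    enriched in abnormal septum orientation and ventricle hypoplasia;
    great-artery malposition tracks final laterality (D-loops essentially
    never show L-malposition and vice versa); apex position tracks looping
    direction.  Association strengths are synthetic.
    """
    return {
        "ivs_orientation": {
            "rightward_congruent": {"normal": 0.80, "superoinferior": 0.10, "strictly_left_right": 0.10},
            "leftward_congruent": {"normal": 0.75, "superoinferior": 0.10, "strictly_left_right": 0.15},
            "revertant": {"normal": 0.35, "superoinferior": 0.40, "strictly_left_right": 0.25},
        },
        "ventricle_hypoplasia": {
            "rightward_congruent": {"balanced": 0.80, "hypoplastic_RV": 0.10, "hypoplastic_LV": 0.10},
            "leftward_congruent": {"balanced": 0.75, "hypoplastic_RV": 0.10, "hypoplastic_LV": 0.15},
            "revertant": {"balanced": 0.40, "hypoplastic_RV": 0.35, "hypoplastic_LV": 0.25},
        },
        "ga_malposition": {
            "rightward_congruent": {"D": 0.70, "L": 0.00, "A": 0.30},
            "leftward_congruent": {"D": 0.00, "L": 0.70, "A": 0.30},
            "revertant": {"D": 0.60, "L": 0.05, "A": 0.35},
        },
        "apex_position": {
            "rightward_congruent": {"levocardia": 0.60, "mesocardia": 0.20, "dextrocardia": 0.20},
            "leftward_congruent": {"levocardia": 0.20, "mesocardia": 0.20, "dextrocardia": 0.60},
            "revertant": {"levocardia": 0.35, "mesocardia": 0.25, "dextrocardia": 0.40},
        },
        "va_connection": {
            "rightward_congruent": {"DORV": 0.55, "TGA": 0.35, "other": 0.10},
            "leftward_congruent": {"DORV": 0.55, "TGA": 0.35, "other": 0.10},
            "revertant": {"DORV": 0.50, "TGA": 0.35, "other": 0.15},
        },
        "trunk_hypoplasia": {
            "rightward_congruent": {"balanced": 0.70, "hypoplastic_aorta": 0.10, "hypoplastic_PT": 0.20},
            "leftward_congruent": {"balanced": 0.60, "hypoplastic_aorta": 0.25, "hypoplastic_PT": 0.15},
            "revertant": {"balanced": 0.60, "hypoplastic_aorta": 0.20, "hypoplastic_PT": 0.20},
        },
        "atrial_situs": {
            g: {"solitus": 0.10, "inversus": 0.05, "right_isomerism": 0.85} for g in TRAJECTORY_GROUPS
        },
        "aortic_arch_side": {
            g: {"left": 0.57, "right": 0.43} for g in TRAJECTORY_GROUPS
        },
        "systemic_venous_return": {
            g: {"normal": 0.6, "abnormal": 0.4} for g in TRAJECTORY_GROUPS
        },
        "pulmonary_venous_return": {
            g: {"normal": 0.6, "abnormal": 0.4} for g in TRAJECTORY_GROUPS
        },
        "bronchial_isomerism": {
            g: {"right_isomerism": 0.95, "normal": 0.05} for g in TRAJECTORY_GROUPS
        },
        "avsd": {g: {"complete": 0.75, "partial": 0.15, "none": 0.10} for g in TRAJECTORY_GROUPS},
        "vsd": {g: {"yes": 0.85, "no": 0.15} for g in TRAJECTORY_GROUPS},
    }


def _default_missing_rates() -> dict[str, float]:
    # mirrors the exclusion pattern of a 43-individual cohort: ~2 unknown
    # looping classes, ~1 unknown laterality, ~3 ambiguous atrial situs
    return {
        "looping_class": 2 / 43,
        "ventricle_laterality": 1 / 43,
        "atrial_situs": 3 / 43,
    }


@dataclass(frozen=True)
class CohortModel:
    """Generative model for a longitudinal categorical cohort.

    ``class_probs`` are the frequencies of looping classes 1-4 (default
    mirrors the 45% leftward / 55% rightward split of the study cohort);
    ``reversion_prob_leftward``/``_rightward`` are the probabilities that
    final ventricle laterality is discordant with the looping direction
    (defaults 11/18 and 1/22); ``feature_tables`` give per-variable category
    probabilities conditional on trajectory group; ``missing_rates`` inject
    unknown/ambiguous codes per variable.
    """

    n: int = 43
    class_probs: tuple[float, float, float, float] = (0.225, 0.275, 0.225, 0.275)
    reversion_prob_leftward: float = 11 / 18
    reversion_prob_rightward: float = 1 / 22
    feature_tables: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=default_feature_tables
    )
    missing_rates: Mapping[str, float] = field(default_factory=_default_missing_rates)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if abs(sum(self.class_probs) - 1.0) > 1e-9 or min(self.class_probs) < 0:
            raise ValueError("class_probs must be non-negative and sum to 1")
        for p in (self.reversion_prob_leftward, self.reversion_prob_rightward):
            if not 0.0 <= p <= 1.0:
                raise ValueError("reversion probabilities must lie in [0, 1]")
        for var, table in self.feature_tables.items():
            for group, probs in table.items():
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9 or min(probs.values()) < -0.0:
                    raise ValueError(
                        f"feature table {var!r}/{group!r} does not sum to 1 (got {total})"
                    )


def simulate_cohort(model: CohortModel, schema: CohortSchema | None = None) -> Cohort:
    """Draw a cohort from the generative model; deterministic under fixed seed."""
    schema = schema or default_schema()
    rng = np.random.default_rng(np.random.SeedSequence(model.seed))
    records = []
    horns = {"L": 0, "R": 0}
    for i in range(model.n):
        looping = str(1 + rng.choice(4, p=np.asarray(model.class_probs)))
        direction = direction_of_class(looping)
        p_rev = (
            model.reversion_prob_leftward
            if direction == "leftward"
            else model.reversion_prob_rightward
        )
        reverted = rng.random() < p_rev
        congruent = CONGRUENT_LATERALITY[direction]
        laterality = ("L" if congruent == "D" else "D") if reverted else congruent
        group = call_trajectory(direction, laterality)

        features: dict[str, str] = {}
        for var in schema.feature_names:
            vs = schema[var]
            if var == "ventricle_laterality":
                features[var] = laterality
                continue
            table = model.feature_tables.get(var)
            if table is None:  # variables without a stated table draw uniformly
                features[var] = str(rng.choice(list(vs.levels)))
            else:
                probs = table[group]
                levels = list(probs)
                features[var] = str(levels[rng.choice(len(levels), p=[probs[l] for l in levels])])

        # missingness injected after the fact, as in annotation failures
        for var, rate in model.missing_rates.items():
            if rng.random() < rate:
                if var == "looping_class":
                    looping = "unknown"
                elif var in features:
                    features[var] = schema[var].missing_codes[-1]

        horn = "L" if rng.random() < 0.5 else "R"
        horns[horn] += 1
        records.append(
            PhenotypeRecord(
                subject_id=f"M{i + 1:03d}",
                uterine_position=f"{horn}{horns[horn]}",
                genotype="mutant",
                looping_class=looping,
                features=features,
            )
        )
    return Cohort(
        records=tuple(records), schema=schema, provenance=f"simulated:seed={model.seed}"
    )


def rightward_probability(model: CohortModel, stage: str = "E9.5") -> float:
    """Population probability of a rightward configuration at a stage.

    Before the remodeling window this is the probability of rightward
    looping (classes 2 and 4); from the window onward it is the probability
    of a final D configuration, i.e. rightward looping that did not revert
    plus leftward looping that did.
    """
    p_right = model.class_probs[1] + model.class_probs[3]
    early = {"E9.5", "E10.5", "E12.5"}
    if stage in early:
        return p_right
    return p_right * (1 - model.reversion_prob_rightward) + (1 - p_right) * (
        model.reversion_prob_leftward
    )


def simulate_stage_counts(
    model: CohortModel,
    stages: Sequence[str] = ("E9.5", "E10.5", "E12.5", "E13.5", "E14.5", "E18.5"),
    n_per_stage: int = 40,
    seed: int | None = None,
) -> list[tuple[str, int, int]]:
    """Independent cross-sectional kinetic cohorts: (stage, n, k_rightward).

    Each stage draws its rightward count from a binomial at the stage's
    population probability under the cohort model, emulating the separately
    collected kinetic cohorts of the study design.
    """
    rng = np.random.default_rng(np.random.SeedSequence(model.seed if seed is None else seed))
    return [
        (stage, n_per_stage, int(rng.binomial(n_per_stage, rightward_probability(model, stage))))
        for stage in stages
    ]


# ---------------------------------------------------------------------------
# 3D landmarks


def _default_group_orientations() -> dict[str, tuple[int, np.ndarray]]:
    """(count, mean septum-normal) per group in the template frame (cc, dv, lr axes).

    Controls sit left-right dominant (a roughly sagittal septum); the case
    mixture mirrors a patient cohort in which most keep a normal position,
    some have superoinferior ventricles (dorsoventral-dominant normal) and
    some strictly left-right ventricles (an extreme left-right normal).
    """
    def u(v):
        v = np.asarray(v, float)
        return v / np.linalg.norm(v)

    return {
        "control": (23, u([0.1, 0.35, 0.93])),
        "case:normal": (27, u([0.1, 0.35, 0.93])),
        "case:superoinferior": (6, u([0.15, 0.93, 0.33])),
        "case:strictly_left_right": (7, u([0.02, 0.05, 0.999])),
    }


@dataclass(frozen=True)
class LandmarkModel:
    """Generative model for synthetic landmark files.

    ``groups`` maps a label to (count, mean unit septum normal) expressed in
    the template's anatomical axes (craniocaudal, dorsoventral, left-right).
    ``angular_noise_deg`` is the angular standard deviation of an isotropic
    perturbation of the normal (0 = exact orientations).  Labels starting
    with ``"case"`` are emitted as cases, everything else as controls.
    """

    groups: Mapping[str, tuple[int, np.ndarray]] = field(
        default_factory=_default_group_orientations
    )
    angular_noise_deg: float = 5.0
    spine_template: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 40.0]])
    )
    dv_template: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 0.0, 20.0], [0.0, 8.0, 21.0]])
    )
    septum_scale: float = 6.0  # spread of the three septum points, same units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.angular_noise_deg < 0:
            raise ValueError("angular noise must be >= 0")
        for label, (count, mean) in self.groups.items():
            mean = np.asarray(mean, float)
            if abs(np.linalg.norm(mean) - 1.0) > 1e-6:
                raise ValueError(f"group {label!r}: mean orientation must be a unit vector")
            if count < 0:
                raise ValueError(f"group {label!r}: negative count")
        spine = np.asarray(self.spine_template, float)
        if np.linalg.norm(spine[1] - spine[0]) == 0:
            raise ValueError("spine template points coincide")


def _perturb_direction(u: np.ndarray, sigma_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Isotropic angular perturbation: tangential Gaussian then renormalize."""
    if sigma_rad == 0.0:
        return u.copy()
    g = rng.standard_normal(3)
    tangent = g - (g @ u) * u
    v = u + sigma_rad * tangent
    return v / np.linalg.norm(v)


def simulate_landmarks(model: LandmarkModel) -> list[LandmarkSet]:
    """Emit landmark sets whose septum plane has the group orientation plus noise.

    The three septum points are placed in the perturbed plane around a fixed
    center; spine and dorsoventral points come straight from the template, so
    every subject shares one anatomical frame.
    """
    rng = np.random.default_rng(np.random.SeedSequence(model.seed))
    frame = build_frame(model.spine_template, model.dv_template)
    axes = np.stack([frame.u_cc, frame.u_dv, frame.u_lr])  # rows
    sigma = np.deg2rad(model.angular_noise_deg)
    center = 0.5 * (np.asarray(model.spine_template[0]) + np.asarray(model.spine_template[1]))

    out: list[LandmarkSet] = []
    counter = 0
    for label, (count, mean) in model.groups.items():
        mean_world = np.asarray(mean, float) @ axes  # components -> world vector
        for _ in range(count):
            counter += 1
            normal = _perturb_direction(mean_world, sigma, rng)
            # orthonormal basis of the septum plane
            helper = np.array([1.0, 0.0, 0.0])
            if abs(normal @ helper) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(normal, helper)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(normal, e1)
            s = model.septum_scale
            septum = np.stack([center + s * e1, center - s * e1 + s * e2, center + s * e2])
            out.append(
                LandmarkSet(
                    subject_id=f"P{counter:03d}",
                    septum_points=septum,
                    spine_points=np.asarray(model.spine_template, float),
                    dv_points=np.asarray(model.dv_template, float),
                    group="control" if not label.startswith("case") else "case",
                    true_label=label,
                )
            )
    return out


# ---------------------------------------------------------------------------
# survival


@dataclass(frozen=True)
class SurvivalModel:
    """Two-or-more-group exponential survival with independent censoring.

    ``group_hazards`` maps group label to a positive event rate (per time
    unit); censoring is exponential at ``censoring_rate`` truncated by an
    administrative ``horizon``.
    """

    group_hazards: Mapping[str, float] = field(
        default_factory=lambda: {"normal_position": 0.05, "abnormal_position": 0.10}
    )
    n_per_group: Mapping[str, int] | int = 20
    censoring_rate: float = 0.02
    horizon: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.group_hazards.values()) <= 0:
            raise ValueError("group hazards must be positive")
        if self.censoring_rate <= 0 or self.horizon <= 0:
            raise ValueError("censoring rate and horizon must be positive")

    def group_n(self, group: str) -> int:
        if isinstance(self.n_per_group, int):
            return self.n_per_group
        return int(self.n_per_group[group])


def simulate_survival(model: SurvivalModel) -> list[SurvivalRecord]:
    """Exponential event times per group, exponentially + administratively censored."""
    rng = np.random.default_rng(np.random.SeedSequence(model.seed))
    records: list[SurvivalRecord] = []
    counter = 0
    for group, hazard in model.group_hazards.items():
        n = model.group_n(group)
        t_event = rng.exponential(1.0 / hazard, size=n)
        t_cens = np.minimum(rng.exponential(1.0 / model.censoring_rate, size=n), model.horizon)
        for te, tc in zip(t_event, t_cens):
            counter += 1
            records.append(
                SurvivalRecord(
                    time=float(min(te, tc)),
                    event=bool(te <= tc),
                    group=group,
                    subject_id=f"S{counter:04d}",
                )
            )
    return records
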