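"""Ventricle position quantified from the orientation of the interventricular septum.

The interventricular septum (IVS) is marked by three 3D points; the unit
normal of the plane through them summarizes where the ventricles sit in the
thorax.  The normal is expressed in an anatomical frame built from two spine
points (craniocaudal axis) and two dorsoventral points (orthogonalized
against the spine), with the left-right axis as their cross product.  The
three components (craniocaudal, dorsoventral, left-right) have unit Euclidean
norm; an individual is called abnormal when a component falls outside the
central 99% empirical interval of a control population, and the abnormality
type follows the dominant component: left-right dominant -> strictly
left-right ventricles, dorsoventral dominant -> superoinferior ventricles.

Sign convention: a plane normal from three unordered points is sign-ambiguous,
so components are canonicalized to the hemisphere with c_lr >= 0 (ties broken
by c_dv >= 0, then c_cc >= 0).  The anatomical meaning of +left-right
(subject's left vs right) is a config flag of the consuming pipeline, since
image axis polarity is scanner-dependent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "LandmarkSet",
    "AnatomicalFrame",
    "IVSOrientation",
    "ControlInterval",
    "MorphometricRatios",
    "plane_normal",
    "build_frame",
    "project_orientation",
    "orientation_from_landmarks",
    "control_interval",
    "classify_orientation",
    "hypoplasia_categories",
]

INPUT_TOL = 1e-6  # unit-norm / orthonormality tolerance on user-supplied vectors
BUILD_TOL = 1e-9  # guaranteed after internal construction

OrientationCategory = Literal[
    "normal", "superoinferior", "strictly_left_right", "abnormal_other"
]


@dataclass(frozen=True)
class LandmarkSet:
    """Raw per-subject landmarks in a consistent length unit.

    ``septum_points``: three points on the IVS plane; ``spine_points``: two
    points along the spine (craniocaudal axis); ``dv_points``: two points
    defining the raw dorsoventral direction.
    """

    subject_id: str
    septum_points: np.ndarray  # (3, 3)
    spine_points: np.ndarray  # (2, 3)
    dv_points: np.ndarray  # (2, 3)
    group: str = "case"  # "control" or "case"
    true_label: str | None = None  # generating category when synthetic

    def __post_init__(self) -> None:
        object.__setattr__(self, "septum_points", np.asarray(self.septum_points, float))
        object.__setattr__(self, "spine_points", np.asarray(self.spine_points, float))
        object.__setattr__(self, "dv_points", np.asarray(self.dv_points, float))
        if self.septum_points.shape != (3, 3):
            raise ValueError("septum_points must be three 3D points")
        if self.spine_points.shape != (2, 3) or self.dv_points.shape != (2, 3):
            raise ValueError("spine_points and dv_points must each be two 3D points")


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal reference frame: craniocaudal, dorsoventral, left-right."""

    u_cc: np.ndarray
    u_dv: np.ndarray
    u_lr: np.ndarray

    def __post_init__(self) -> None:
        for name in ("u_cc", "u_dv", "u_lr"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))

    def check(self, tol: float = BUILD_TOL) -> None:
        axes = np.stack([self.u_cc, self.u_dv, self.u_lr])
        gram = axes @ axes.T
        if not np.allclose(gram, np.eye(3), atol=tol):
            raise ValueError("frame is not orthonormal within tolerance")


@dataclass(frozen=True)
class IVSOrientation:
    """Unit components of the septum-plane normal in the anatomical frame."""

    c_cc: float
    c_dv: float
    c_lr: float
    subject_id: str = ""
    group: str = ""

    @property
    def components(self) -> np.ndarray:
        return np.array([self.c_cc, self.c_dv, self.c_lr])


@dataclass(frozen=True)
class ControlInterval:
    """Per-component central empirical interval of control orientations."""

    lower: np.ndarray  # (3,) in (c_cc, c_dv, c_lr) order
    upper: np.ndarray
    n_controls: int
    coverage: float = 0.99

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, float))
        object.__setattr__(self, "upper", np.asarray(self.upper, float))
        if np.any(self.lower > self.upper):
            raise ValueError("interval lower bound exceeds upper bound")

    def contains(self, o: IVSOrientation) -> np.ndarray:
        c = o.components
        return (c >= self.lower) & (c <= self.upper)


@dataclass(frozen=True)
class MorphometricRatios:
    """Size ratios used to grade hypoplasia.

    ``ventricle_volume_ratio``: right over left ventricle outer volume;
    ``valve_diameter_ratio``: aortic over pulmonary valve diameter.
    """

    ventricle_volume_ratio: float
    valve_diameter_ratio: float

    def __post_init__(self) -> None:
        if self.ventricle_volume_ratio <= 0 or self.valve_diameter_ratio <= 0:
            raise ValueError("morphometric ratios must be positive")


# ---------------------------------------------------------------------------


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"{what}: zero vector")
    return v / n


def _canonical_sign(components: np.ndarray) -> np.ndarray:
    """Flip the whole component vector into the canonical hemisphere.

    c_lr >= 0, residual ties broken by c_dv >= 0 then c_cc >= 0 (component
    order is (c_cc, c_dv, c_lr)).
    """
    for idx in (2, 1, 0):
        if components[idx] > 0:
            return components
        if components[idx] < 0:
            return -components
    return components


def plane_normal(p1, p2, p3) -> np.ndarray:
    """Unit normal of the plane through three non-collinear points.

    Computed as the normalized cross product of the two edge vectors; the
    sign is canonicalized (largest-magnitude coordinate positive) so the
    result does not depend on the labelling order of the points.
    """
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    v1, v2 = p2 - p1, p3 - p1
    n = np.cross(v1, v2)
    scale = max(np.linalg.norm(v1), np.linalg.norm(v2))
    if scale == 0 or np.linalg.norm(n) < 1e-12 * scale**2 or np.linalg.norm(n) == 0:
        raise ValueError("septum points are collinear or coincident")
    n = n / np.linalg.norm(n)
    dominant = int(np.argmax(np.abs(n)))
    return n if n[dominant] > 0 else -n


def build_frame(spine_points, dv_points) -> AnatomicalFrame:
    """Anatomical frame from spine and dorsoventral landmark pairs.

    The craniocaudal axis is the normalized spine direction; the raw
    dorsoventral direction is orthogonalized against it (exact 90 degrees by
    construction); the left-right axis is their cross product, making the
    frame right-handed.
    """
    spine_points = np.asarray(spine_points, float)
    dv_points = np.asarray(dv_points, float)
    u_cc = _unit(spine_points[1] - spine_points[0], "spine direction")
    raw_dv = dv_points[1] - dv_points[0]
    raw_norm = np.linalg.norm(raw_dv)
    if raw_norm == 0:
        raise ValueError("dorsoventral points coincide")
    residual = raw_dv - (raw_dv @ u_cc) * u_cc
    if np.linalg.norm(residual) < 1e-8 * raw_norm:
        raise ValueError("dorsoventral direction is parallel to the spine")
    u_dv = residual / np.linalg.norm(residual)
    u_lr = np.cross(u_cc, u_dv)
    frame = AnatomicalFrame(u_cc=u_cc, u_dv=u_dv, u_lr=u_lr)
    frame.check(BUILD_TOL)
    return frame


def project_orientation(
    normal: np.ndarray,
    frame: AnatomicalFrame,
    subject_id: str = "",
    group: str = "",
) -> IVSOrientation:
    """Dot the septum normal onto each frame axis; components have unit norm.

    Inputs are checked for unit norm and orthonormality at 1e-6; the output
    sign is canonicalized (c_lr >= 0, ties by c_dv then c_cc).
    """
    normal = np.asarray(normal, float)
    if abs(np.linalg.norm(normal) - 1.0) > INPUT_TOL:
        raise ValueError("septum normal must be a unit vector")
    frame.check(INPUT_TOL)
    comps = np.array([normal @ frame.u_cc, normal @ frame.u_dv, normal @ frame.u_lr])
    comps = _canonical_sign(comps)
    return IVSOrientation(
        c_cc=float(comps[0]), c_dv=float(comps[1]), c_lr=float(comps[2]),
        subject_id=subject_id, group=group,
    )


def orientation_from_landmarks(lm: LandmarkSet) -> IVSOrientation:
    """Full per-subject computation: plane normal, frame, projection."""
    normal = plane_normal(*lm.septum_points)
    frame = build_frame(lm.spine_points, lm.dv_points)
    return project_orientation(normal, frame, subject_id=lm.subject_id, group=lm.group)


def control_interval(
    orientations: Sequence[IVSOrientation],
    coverage: float = 0.99,
    min_controls: int = 10,
) -> ControlInterval:
    """Central empirical interval of control components at the given coverage.

    Quantiles at (1-coverage)/2 and 1-(1-coverage)/2 per component, with
    linear interpolation between order statistics.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if len(orientations) < min_controls:
        raise ValueError(
            f"need at least {min_controls} control orientations, got {len(orientations)}"
        )
    comps = np.stack([o.components for o in orientations])
    alpha = (1.0 - coverage) / 2.0
    lower = np.quantile(comps, alpha, axis=0, method="linear")
    upper = np.quantile(comps, 1.0 - alpha, axis=0, method="linear")
    return ControlInterval(lower=lower, upper=upper, n_controls=len(orientations), coverage=coverage)


def classify_orientation(o: IVSOrientation, ref: ControlInterval) -> OrientationCategory:
    """Call ventricle position against the control reference interval.

    Normal when every component lies inside the interval.  Otherwise the
    call follows the component of highest absolute value: left-right ->
    strictly left-right ventricles, dorsoventral -> superoinferior
    ventricles; a craniocaudal-dominant abnormal vector is recorded as
    ``abnormal_other`` rather than forced into either class.
    """
    if bool(np.all(ref.contains(o))):
        return "normal"
    dominant = int(np.argmax(np.abs(o.components)))  # 0=cc, 1=dv, 2=lr
    if dominant == 2:
        return "strictly_left_right"
    if dominant == 1:
        return "superoinferior"
    return "abnormal_other"


def hypoplasia_categories(
    ratios: MorphometricRatios,
    ventricle_interval: tuple[float, float],
    valve_interval: tuple[float, float],
) -> tuple[str, str]:
    """Grade ventricle and arterial-trunk hypoplasia from size ratios.

    The ventricle ratio is RV/LV outer volume: below the reference interval
    the numerator organ (RV) is hypoplastic, above it the denominator (LV).
    The valve ratio is aortic/pulmonary diameter: below -> hypoplastic
    aorta, above -> hypoplastic pulmonary trunk.  Reference intervals are
    config (typically the control 99% interval of each ratio).
    """
    def grade(value: float, interval: tuple[float, float], low_cat: str, high_cat: str) -> str:
        lo, hi = interval
        if lo > hi:
            raise ValueError("threshold interval is inverted")
        if value < lo:
            return low_cat
        if value > hi:
            return high_cat
        return "balanced"

    ventricle = grade(
        ratios.ventricle_volume_ratio, ventricle_interval, "hypoplastic_RV", "hypoplastic_LV"
    )
    valve = grade(ratios.valve_diameter_ratio, valve_interval, "hypoplastic_aorta", "hypoplastic_PT")
    return ventricle, valve


# ---------------------------------------------------------------------------
# landmark JSON I/O


def landmarks_to_json(sets: Iterable[LandmarkSet], units: str = "mm") -> list[dict]:
    out = []
    for lm in sets:
        entry = {
            "id": lm.subject_id,
            "group": lm.group,
            "septum": lm.septum_points.tolist(),
            "spine": lm.spine_points.tolist(),
            "dv": lm.dv_points.tolist(),
            "units": units,
        }
        if lm.true_label is not None:
            entry["true_label"] = lm.true_label
        out.append(entry)
    return out


def landmarks_from_json(payload: Iterable[dict]) -> list[LandmarkSet]:
    return [
        LandmarkSet(
            subject_id=entry["id"],
            septum_points=np.asarray(entry["septum"], float),
            spine_points=np.asarray(entry["spine"], float),
            dv_points=np.asarray(entry["dv"], float),
            group=entry.get("group", "case"),
            true_label=entry.get("true_label"),
        )
        for entry in payload
    ]
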