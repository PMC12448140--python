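import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from looptrax.geometry import (
    AnatomicalFrame,
    ControlInterval,
    IVSOrientation,
    MorphometricRatios,
    build_frame,
    classify_orientation,
    control_interval,
    hypoplasia_categories,
    landmarks_from_json,
    landmarks_to_json,
    orientation_from_landmarks,
    plane_normal,
    project_orientation,
)
from looptrax.simulate import LandmarkModel, simulate_landmarks

finite = st.floats(-10, 10, allow_nan=False)
point = st.tuples(finite, finite, finite).map(np.array)


class TestPlaneNormal:
    def test_axis_aligned_plane(self):
        n = plane_normal((0, 0, 0), (1, 0, 0), (0, 1, 0))
        assert np.allclose(n, [0, 0, 1])

    def test_scale_invariance(self):
        n = plane_normal((0, 0, 0), (2, 0, 0), (0, 3, 0))
        assert np.allclose(n, [0, 0, 1])

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            plane_normal((0, 0, 0), (1, 1, 1), (2, 2, 2))

    @settings(derandomize=True, max_examples=60)
    @given(p1=point, p2=point, p3=point, perm=st.permutations([0, 1, 2]))
    def test_relabeling_invariance(self, p1, p2, p3, perm):
        pts = [p1, p2, p3]
        try:
            base = plane_normal(*pts)
        except ValueError:
            return
        shuffled = plane_normal(*(pts[i] for i in perm))
        assert np.allclose(base, shuffled, atol=1e-9)


class TestBuildFrame:
    def test_known_hand_computed_frame(self):
        # spine along +z, raw dorsoventral (0, 1, 0.5): the craniocaudal
        # component is stripped, and u_lr = u_cc x u_dv = (-1, 0, 0)
        frame = build_frame([(0, 0, 0), (0, 0, 2)], [(0, 0, 0), (0, 1, 0.5)])
        assert np.allclose(frame.u_cc, [0, 0, 1], atol=1e-12)
        assert np.allclose(frame.u_dv, [0, 1, 0], atol=1e-12)
        assert np.allclose(frame.u_lr, [-1, 0, 0], atol=1e-12)

    def test_orthogonal_dv_is_fixed_point(self):
        frame = build_frame([(0, 0, 0), (0, 0, 1)], [(0, 0, 0), (0, 2, 0)])
        assert np.allclose(frame.u_dv, [0, 1, 0], atol=1e-12)

    def test_dv_parallel_to_spine_rejected(self):
        with pytest.raises(ValueError, match="parallel"):
            build_frame([(0, 0, 0), (0, 0, 1)], [(1, 1, 0), (1, 1, 5)])

    @settings(derandomize=True, max_examples=60)
    @given(data=st.data())
    def test_frames_orthonormal_to_build_tolerance(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        spine = rng.normal(size=(2, 3))
        dv = rng.normal(size=(2, 3))
        try:
            frame = build_frame(spine, dv)
        except ValueError:
            return
        axes = np.stack([frame.u_cc, frame.u_dv, frame.u_lr])
        assert np.allclose(axes @ axes.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(axes) == pytest.approx(1.0, abs=1e-9)


class TestProjection:
    def frame(self):
        return build_frame([(0, 0, 0), (0, 0, 1)], [(0, 0, 0), (0, 1, 0)])

    def test_left_right_normal_projects_to_unit_lr(self):
        frame = self.frame()
        o = project_orientation(frame.u_lr, frame)
        assert (o.c_cc, o.c_dv, o.c_lr) == pytest.approx((0, 0, 1), abs=1e-12)

    def test_diagonal_normal_splits_components(self):
        frame = self.frame()
        normal = (frame.u_cc + frame.u_dv) / np.sqrt(2)
        o = project_orientation(normal, frame)
        assert (o.c_cc, o.c_dv) == pytest.approx((np.sqrt(2) / 2, np.sqrt(2) / 2), abs=1e-12)

    def test_sign_canonicalization_flips_into_lr_positive_hemisphere(self):
        frame = self.frame()
        o = project_orientation(-frame.u_lr, frame)
        assert o.c_lr == pytest.approx(1.0)

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            project_orientation(np.array([0.0, 0.0, 2.0]), self.frame())

    @settings(derandomize=True, max_examples=100)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_projection_preserves_unit_norm(self, seed):
        rng = np.random.default_rng(seed)
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        try:
            frame = build_frame(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        except ValueError:
            return
        o = project_orientation(normal, frame)
        assert np.linalg.norm(o.components) == pytest.approx(1.0, abs=1e-9)


class TestControlInterval:
    def orientations(self, comps):
        return [IVSOrientation(*c) for c in comps]

    def test_quantile_interval_of_23_controls(self):
        rng = np.random.default_rng(0)
        comps = rng.normal(size=(23, 3))
        comps /= np.linalg.norm(comps, axis=1, keepdims=True)
        ref = control_interval(self.orientations(comps), coverage=0.99)
        for k in range(3):
            assert ref.lower[k] == pytest.approx(np.quantile(comps[:, k], 0.005))
            assert ref.upper[k] == pytest.approx(np.quantile(comps[:, k], 0.995))

    def test_identical_controls_give_degenerate_interval(self):
        comps = np.tile([0.1, 0.2, np.sqrt(1 - 0.05)], (12, 1))
        ref = control_interval(self.orientations(comps))
        assert np.allclose(ref.lower, ref.upper)

    def test_full_coverage_is_min_max(self):
        rng = np.random.default_rng(1)
        comps = rng.normal(size=(15, 3))
        ref = control_interval(self.orientations(comps), coverage=1.0)
        assert np.allclose(ref.lower, comps.min(axis=0))
        assert np.allclose(ref.upper, comps.max(axis=0))

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            control_interval(self.orientations(np.eye(3)))


class TestClassification:
    ref = ControlInterval(
        lower=np.array([-0.2, 0.1, 0.8]), upper=np.array([0.3, 0.5, 1.0]), n_controls=23
    )

    def test_inside_interval_is_normal(self):
        assert classify_orientation(IVSOrientation(0.0, 0.3, 0.954), self.ref) == "normal"

    def test_dorsoventral_dominant_outlier_is_superoinferior(self):
        o = IVSOrientation(0.1, 0.9, 0.42)
        assert classify_orientation(o, self.ref) == "superoinferior"

    def test_left_right_dominant_outlier_is_strictly_left_right(self):
        o = IVSOrientation(0.1, 0.05, 0.994)
        assert classify_orientation(o, self.ref) == "strictly_left_right"

    def test_craniocaudal_dominant_outlier_is_other(self):
        o = IVSOrientation(0.9, 0.3, 0.32)
        assert classify_orientation(o, self.ref) == "abnormal_other"

    def test_rigid_rotation_invariance(self):
        """Rotating a subject's landmarks rigidly leaves the call unchanged."""
        model = LandmarkModel(seed=21)
        sets = simulate_landmarks(model)
        controls = [orientation_from_landmarks(s) for s in sets if s.group == "control"]
        ref = control_interval(controls)
        rng = np.random.default_rng(17)
        # random rotation matrix via QR
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        shift = rng.normal(size=3)
        for lm in sets[:30]:
            base = classify_orientation(orientation_from_landmarks(lm), ref)
            rotated = type(lm)(
                subject_id=lm.subject_id,
                septum_points=lm.septum_points @ Q.T + shift,
                spine_points=lm.spine_points @ Q.T + shift,
                dv_points=lm.dv_points @ Q.T + shift,
                group=lm.group,
            )
            assert classify_orientation(orientation_from_landmarks(rotated), ref) == base

    def test_zero_noise_recovery_of_generating_category(self):
        """Noise-free landmarks must reproduce the generating group for every
        case whose generating orientation lies outside the control interval."""
        model = LandmarkModel(angular_noise_deg=0.0, seed=33)
        sets = simulate_landmarks(model)
        controls = [orientation_from_landmarks(s) for s in sets if s.group == "control"]
        ref = control_interval(controls)
        for lm in sets:
            if lm.group == "control":
                continue
            o = orientation_from_landmarks(lm)
            generating = np.asarray(model.groups[lm.true_label][1])
            outside = not np.all(
                (generating >= ref.lower) & (generating <= ref.upper)
            )
            if outside:
                assert classify_orientation(o, ref) == lm.true_label.split(":", 1)[1]


class TestHypoplasia:
    def test_balanced_inside_interval(self):
        r = MorphometricRatios(ventricle_volume_ratio=1.0, valve_diameter_ratio=1.0)
        assert hypoplasia_categories(r, (0.7, 1.4), (0.8, 1.3)) == ("balanced", "balanced")

    def test_low_ventricle_ratio_is_hypoplastic_rv(self):
        r = MorphometricRatios(ventricle_volume_ratio=0.4, valve_diameter_ratio=1.0)
        assert hypoplasia_categories(r, (0.7, 1.4), (0.8, 1.3))[0] == "hypoplastic_RV"

    def test_high_valve_ratio_is_hypoplastic_pt(self):
        r = MorphometricRatios(ventricle_volume_ratio=1.0, valve_diameter_ratio=2.0)
        assert hypoplasia_categories(r, (0.7, 1.4), (0.8, 1.3))[1] == "hypoplastic_PT"

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            MorphometricRatios(ventricle_volume_ratio=0.0, valve_diameter_ratio=1.0)


def test_landmark_json_round_trip():
    sets = simulate_landmarks(LandmarkModel(seed=4))
    back = landmarks_from_json(landmarks_to_json(sets))
    for a, b in zip(sets, back):
        assert a.subject_id == b.subject_id and a.group == b.group
        assert np.array_equal(a.septum_points, b.septum_points)
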