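"""Kinematic feature extraction checked against analytic and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import wristkin as wk
from wristkin.errors import DegenerateInputError, InsufficientDataError
from wristkin.features import VelocityProfile, _distances_to_curve

from conftest import line_recording


def densify_curve(curve, n=100_000):
    """Arc-length-dense point cloud on the closed curve (oracle helper)."""
    closed = np.vstack([curve.vertices, curve.vertices[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.linspace(0, cum[-1], n)
    return np.column_stack(
        [np.interp(s, cum, closed[:, 0]), np.interp(s, cum, closed[:, 1])]
    )


class TestVelocityProfile:
    def test_uniform_motion(self):
        rec = line_recording([(i - 4.5, 0.0) for i in range(10)])
        prof = wk.compute_velocity_profile(rec, smooth_window=0)
        np.testing.assert_allclose(prof.speeds, 1.0)
        np.testing.assert_allclose(prof.accel_mags[1:-1], 0.0, atol=1e-12)

    def test_stationary(self):
        rec = line_recording([(1.0, 1.0)] * 8)
        prof = wk.compute_velocity_profile(rec, smooth_window=0)
        np.testing.assert_allclose(prof.speeds, 0.0)
        np.testing.assert_allclose(prof.accel_mags, 0.0)

    def test_quadratic_matches_analytic_derivative(self):
        t = np.arange(0, 1.0001, 0.01)
        rec = wk.TrajectoryRecording("s", "right", "square", 0.0, t, t**2, 0 * t)
        prof = wk.compute_velocity_profile(rec, smooth_window=0)
        np.testing.assert_allclose(prof.speeds[1:-1], 2 * t[1:-1], atol=1e-3)

    def test_uniform_circular_motion_oracle(self):
        # radius 4 cm, period 8 s: speed 2*pi*4/8, accel v^2/r
        t = np.arange(0, 8, 0.002)
        theta = 2 * np.pi * t / 8
        rec = wk.TrajectoryRecording(
            "s", "right", "circle", 0.0, t, 4 * np.cos(theta), 4 * np.sin(theta)
        )
        prof = wk.compute_velocity_profile(rec, smooth_window=0)
        v = 2 * np.pi * 4 / 8
        assert wk.average_velocity(prof) == pytest.approx(v, rel=0.01)
        assert wk.average_acceleration(prof) == pytest.approx(v**2 / 4, rel=0.02)

    def test_requires_three_samples(self):
        wk.compute_velocity_profile(line_recording([(0, 0), (1, 0), (2, 0)]))

        class Stub:  # the recording type itself already enforces >= 3 samples
            n_samples = 2

        with pytest.raises(InsufficientDataError):
            wk.compute_velocity_profile(Stub())


def _profile(speeds):
    speeds = np.asarray(speeds, dtype=float)
    return VelocityProfile(
        times=np.arange(len(speeds), dtype=float),
        speeds=speeds,
        accel_mags=np.zeros_like(speeds),
    )


class TestNPV:
    def test_constant_speed_zero_in_both_modes(self):
        prof = _profile([2, 2, 2, 2])
        assert wk.count_peak_velocity_points(prof, "peaks") == 0
        assert wk.count_peak_velocity_points(prof, "literal") == 0

    def test_alternating_speeds(self):
        prof = _profile([1, 3, 1, 3, 1])  # mean 1.8, two local maxima
        assert wk.count_peak_velocity_points(prof, "peaks") == 2
        assert wk.count_peak_velocity_points(prof, "literal") == 2

    def test_monotone_ramp(self):
        prof = _profile([1, 2, 3])  # mean 2; endpoint is not a strict maximum
        assert wk.count_peak_velocity_points(prof, "literal") == 1
        assert wk.count_peak_velocity_points(prof, "peaks") == 0


class TestDeviation:
    def test_on_curve_is_zero(self, square_curve):
        rec = line_recording(square_curve.vertices, dt=0.1)
        assert wk.trajectory_deviation(rec, square_curve) == 0.0

    def test_concentric_circle_offset(self, circle_curve):
        theta = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        rec = line_recording(
            np.column_stack([4.5 * np.cos(theta), 4.5 * np.sin(theta)]), dt=0.02
        )
        assert wk.trajectory_deviation(rec, circle_curve) == pytest.approx(0.5, abs=1e-3)

    def test_matches_densification_brute_force(self, square_curve):
        rec = wk.simulate_trajectory(square_curve, wk.profile_from_score(8, 21), 0.0)
        tree = cKDTree(densify_curve(square_curve))
        oracle = float(np.mean(tree.query(rec.positions)[0]))
        assert wk.trajectory_deviation(rec, square_curve) == pytest.approx(oracle, abs=1e-4)


class TestCoincidence:
    def test_identical_path_full_coincidence(self, circle_curve):
        rec = line_recording(circle_curve.vertices, dt=0.01)
        assert wk.trajectory_coincidence(rec, circle_curve) == 100.0

    def test_everywhere_far_gives_zero(self, circle_curve):
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        rec = line_recording(
            np.column_stack([1.0 * np.cos(theta), 1.0 * np.sin(theta)]), dt=0.01
        )
        assert wk.trajectory_coincidence(rec, circle_curve, epsilon=0.25) == 0.0

    def test_half_on_half_off(self, square_curve):
        # first half: two laps exactly on a radius-2 circle curve; second
        # half: the same path length on a concentric circle offset outward
        # by 10 * epsilon.  C -> 50% as the halves dominate the connector.
        eps = 0.25
        curve = wk.make_task_curve("circle", 4, 720)  # radius 2
        half_len = 2 * (2 * np.pi * 2)  # two laps
        theta_on = np.linspace(np.pi / 2, np.pi / 2 - half_len / 2, 2000)
        on = np.column_stack([2 * np.cos(theta_on), 2 * np.sin(theta_on)])
        r_off = 2 + 10 * eps
        theta_off = np.linspace(theta_on[-1], theta_on[-1] - half_len / r_off, 2000)
        off = np.column_stack([r_off * np.cos(theta_off), r_off * np.sin(theta_off)])
        connector = np.linspace(on[-1], off[0], 50)
        rec = line_recording(np.vstack([on, connector, off]), dt=0.001)
        c = wk.trajectory_coincidence(rec, curve, epsilon=eps)
        assert c == pytest.approx(50.0, abs=2.5)

    def test_zero_length_path_is_degenerate(self, square_curve):
        rec = line_recording([(0.0, 0.0)] * 5)
        with pytest.raises(DegenerateInputError):
            wk.trajectory_coincidence(rec, square_curve)


class TestIntersectionArea:
    def test_identical_regions_zero(self, square_curve):
        rec = line_recording(square_curve.vertices, dt=0.01)
        assert wk.intersection_area(rec, square_curve) == pytest.approx(0.0, abs=1e-9)

    def test_nested_squares(self):
        curve = wk.make_task_curve("square", 4, 80)
        inner = wk.make_task_curve("square", 2, 80)
        rec = line_recording(inner.vertices, dt=0.01)
        assert wk.intersection_area(rec, curve) == pytest.approx(16 - 4, rel=1e-6)

    def test_degenerate_path_counts_as_full_miss(self, square_curve):
        rec = line_recording([(0, 0), (1, 0), (2, 0), (3, 0)])
        with pytest.warns(RuntimeWarning):
            area = wk.intersection_area(rec, square_curve)
        assert area == pytest.approx(square_curve.polygon.area)

    def test_matches_monte_carlo_rasterization(self, circle_curve):
        from matplotlib.path import Path as MplPath

        rec = wk.simulate_trajectory(circle_curve, wk.profile_from_score(12, 3), 0.0)
        rng = np.random.default_rng(0)
        lo, hi = -5.5, 5.5
        pts = rng.uniform(lo, hi, size=(1_000_000, 2))
        in_curve = MplPath(circle_curve.vertices).contains_points(pts)
        in_traj = MplPath(rec.positions).contains_points(pts)
        mc = np.mean(in_curve ^ in_traj) * (hi - lo) ** 2
        assert wk.intersection_area(rec, circle_curve) == pytest.approx(mc, rel=0.02)


class TestExtractFeatures:
    def test_healthy_recording_near_perfect(self, square_curve, healthy_recording):
        fv = wk.extract_features(healthy_recording, square_curve)
        assert fv.C >= 99.0
        assert fv.D <= 0.05

    def test_deterministic(self, square_curve, impaired_recording):
        a = wk.extract_features(impaired_recording, square_curve)
        b = wk.extract_features(impaired_recording, square_curve)
        assert a == b

    def test_impairment_degrades_features(
        self, square_curve, healthy_recording, impaired_recording
    ):
        h = wk.extract_features(healthy_recording, square_curve)
        i = wk.extract_features(impaired_recording, square_curve)
        assert i.D > h.D
        assert i.S > h.S
        assert i.C < h.C

    def test_full_coincidence_bounds_deviation(self, square_curve, healthy_recording):
        params = wk.ExtractionParams(epsilon=0.25)
        fv = wk.extract_features(healthy_recording, square_curve, params)
        assert fv.C == 100.0
        assert fv.D <= params.epsilon

    def test_rigid_motion_invariance(self, circle_curve):
        rec = wk.simulate_trajectory(circle_curve, wk.profile_from_score(14, 8), 0.0)
        angle = np.deg2rad(17.0)
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        rec_rot = wk.TrajectoryRecording(
            rec.subject_id, rec.hand, rec.shape_id, rec.force_mode,
            rec.times, *(rec.positions @ rot.T).T,
        )
        curve_rot = wk.TaskCurve(
            circle_curve.shape_id, circle_curve.vertices @ rot.T, circle_curve.size_cm
        )
        a = wk.extract_features(rec, circle_curve).as_array()
        b = wk.extract_features(rec_rot, curve_rot).as_array()
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-9)

    def test_feature_score_sign_structure(self, small_feature_table):
        """C correlates positively with the score; D, S, T, NPV negatively."""
        corr = small_feature_table[list(wk.FEATURE_NAMES) + ["score"]].corr()["score"]
        assert corr["C"] > 0.5
        for name in ("D", "S", "T", "NPV"):
            assert corr[name] < -0.5
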