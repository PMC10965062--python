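"""Pixel-to-meter scaling, sagittal step lengths, joint angles, and trunk
inclination."""

import numpy as np
import pytest

import videogait as vg
from videogait import body25
from videogait.core import TrialKeypoints
from videogait.events import GaitEvents
from videogait.sagittal import (
    ScaleFactor,
    joint_angles,
    sagittal_step_table,
    scale_factor,
    trunk_inclination,
)


class TestScaleFactor:
    def test_simple_division(self):
        assert scale_factor(1.0, 100.0).meters_per_pixel == pytest.approx(0.01)

    def test_walkway_calibration(self):
        assert scale_factor(4.83, 966.0).meters_per_pixel == pytest.approx(0.005)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            scale_factor(0.0, 100.0)
        with pytest.raises(ValueError):
            ScaleFactor(meters_per_pixel=-1.0)

    def test_simulator_scale_matches_camera_geometry(self, default_walk):
        """The synthetic CameraSetup's calibration reproduces the analytic
        depth/focal-length ratio at the walking plane to within 0.5%."""
        spec, points, truth = default_walk
        cam, setup = vg.sagittal_camera(spec, truth, distance_m=4.0, f_px=1400.0)
        scale = scale_factor(setup.calibration_distance_m, setup.calibration_distance_px)
        assert scale.meters_per_pixel == pytest.approx(4.0 / 1400.0, rel=0.005)


def _leg_track(points_by_kp, n=2):
    xy = np.zeros((n, body25.N_KEYPOINTS, 2))
    conf = np.ones((n, body25.N_KEYPOINTS))
    for kp, p in points_by_kp.items():
        xy[:, kp] = p
    return TrialKeypoints(xy=xy, confidence=conf, fps=30.0, view="sagittal")


class TestStepTable:
    def test_ankle_distance_definition(self):
        track = _leg_track({body25.L_ANKLE: (220, 0), body25.R_ANKLE: (100, 0)}, n=60)
        events = GaitEvents(heel_strikes_left=[1.0], heel_strikes_right=[0.5])
        steps = sagittal_step_table(
            track, events, ScaleFactor(0.005), "ankle_distance"
        )
        assert steps.iloc[0]["step_length_m"] == pytest.approx(0.60)
        assert steps.iloc[0]["side"] == "left"

    def test_unknown_method_rejected(self, sagittal_trial):
        track, _, _ = sagittal_trial
        with pytest.raises(ValueError, match="method"):
            sagittal_step_table(track, GaitEvents([], []), ScaleFactor(0.005), "hips")

    def test_noiseless_recovery_of_commanded_step_length(self):
        """An in-plane walker (zero step width: no out-of-plane
        perspective) recovers the commanded step length within 0.01 m."""
        from conftest import matched_steady_steps
        from videogait.pipeline import analyze_sagittal_track

        spec = vg.WalkerSpec(step_width_m=0.0)
        points, truth = vg.simulate_walk(spec)
        cam, setup = vg.sagittal_camera(spec, truth)
        track = vg.to_gait_coordinates(vg.project(points, cam, spec.fps), setup)
        res = analyze_sagittal_track(track, setup, trim_steps=0)
        steps = matched_steady_steps(res.steps, res.events, truth)
        assert abs(steps["step_length_m"].mean() - spec.step_length_m) < 0.01

    def test_realistic_stance_width_small_perspective_bias(self, sagittal_trial):
        """With a realistic step width the single-scale-factor approach
        leaves a small out-of-plane error (uncorrected, as in practice)."""
        from conftest import matched_steady_steps
        from videogait.pipeline import analyze_sagittal_track

        track, setup, truth = sagittal_trial
        res = analyze_sagittal_track(track, setup, trim_steps=0)
        steps = matched_steady_steps(res.steps, res.events, truth)
        assert abs(steps["step_length_m"].mean() - truth.spec.step_length_m) < 0.025

    def test_torso_travel_exceeds_ankle_distance(self, sagittal_trial):
        """Torso travel per step is systematically longer than the ankle
        separation at heel-strike (the trailing ankle has already rolled
        forward); only the sign of the difference is asserted."""
        from videogait.pipeline import analyze_sagittal_track

        track, setup, truth = sagittal_trial
        ankle = analyze_sagittal_track(track, setup, step_length_method="ankle_distance")
        torso = analyze_sagittal_track(track, setup, step_length_method="torso_travel")
        diff = (
            torso.steps[torso.steps["valid"]]["step_length_m"].mean()
            - ankle.steps[ankle.steps["valid"]]["step_length_m"].mean()
        )
        assert diff > 0

    def test_step_count_identical_across_methods(self, sagittal_trial):
        from videogait.pipeline import analyze_sagittal_track

        track, setup, _ = sagittal_trial
        a = analyze_sagittal_track(track, setup, step_length_method="ankle_distance")
        b = analyze_sagittal_track(track, setup, step_length_method="torso_travel")
        assert a.steps["valid"].sum() == b.steps["valid"].sum()


class TestJointAngles:
    def test_neutral_pose_anchors(self):
        """Vertical thigh and shank with a horizontal foot: all angles 0."""
        track = _leg_track({
            body25.L_HIP: (0, 100), body25.L_KNEE: (0, 55),
            body25.L_ANKLE: (0, 10), body25.L_BIG_TOE: (15, 10),
            body25.R_HIP: (0, 100), body25.R_KNEE: (0, 55),
            body25.R_ANKLE: (0, 10), body25.R_BIG_TOE: (15, 10),
        })
        angles = joint_angles(track)
        for name in ("hip_left", "knee_left", "ankle_left", "knee_right"):
            np.testing.assert_allclose(getattr(angles, name), 0.0, atol=1e-9)

    def test_knee_flexion_from_interior_angle(self):
        """Thigh-shank interior angle of 150° is 30° of knee flexion."""
        hip = np.array([0.0, 100.0])
        knee = np.array([10.0, 55.0])
        thigh_dir = (knee - hip) / np.linalg.norm(knee - hip)
        # rotate the extended thigh line by 30° (flexion bends the shank back)
        ang = np.radians(-30.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        ankle = knee + 45 * (rot @ thigh_dir)
        track = _leg_track({
            body25.L_HIP: hip, body25.L_KNEE: knee, body25.L_ANKLE: ankle,
            body25.L_BIG_TOE: ankle + (15, 0),
        })
        angles = joint_angles(track)
        np.testing.assert_allclose(angles.knee_left, 30.0, atol=1e-9)

    def test_invariance_to_translation_and_scale(self, sagittal_trial):
        track, _, _ = sagittal_trial
        moved = track.copy()
        moved.xy = moved.xy * 2.5 + np.array([100.0, -40.0])
        a, b = joint_angles(track), joint_angles(moved)
        for name in ("hip_left", "knee_right", "ankle_left"):
            np.testing.assert_allclose(getattr(a, name), getattr(b, name), atol=1e-9)

    def test_horizontal_mirror_flips_flexion_sign(self, sagittal_trial):
        track, _, _ = sagittal_trial
        mirrored = track.copy()
        mirrored.xy[:, :, 0] *= -1
        a, b = joint_angles(track), joint_angles(mirrored)
        np.testing.assert_allclose(a.hip_left, -b.hip_left, atol=1e-9)
        np.testing.assert_allclose(a.knee_right, -b.knee_right, atol=1e-9)
        # the ankle angle is a magnitude-of-deviation measure: mirror-invariant
        np.testing.assert_allclose(a.ankle_left, b.ankle_left, atol=1e-9)

    def test_simulator_angle_recovery(self, sagittal_trial):
        """Pipeline angles match generator ground truth within 1° MAE over
        steady gait cycles."""
        from videogait.agreement import kinematic_mae
        from videogait.pipeline import analyze_sagittal_track
        from conftest import steady_heel_strikes

        track, setup, truth = sagittal_trial
        res = analyze_sagittal_track(track, setup)
        steady = steady_heel_strikes(truth)
        for joint in ("hip", "knee", "ankle"):
            for side in ("left", "right"):
                hs = steady[side]
                cycles = [(hs[i], hs[i + 1]) for i in range(len(hs) - 1)]
                mae = kinematic_mae(
                    res.angles.get(joint, side), truth.angles.get(joint, side),
                    setup.fps, cycles,
                )
                assert mae < 1.0, f"{joint} {side}: {mae:.2f}°"


class TestTrunkInclination:
    def test_vertical_trunk_minus_offset(self):
        track = _leg_track({body25.NECK: (0, 200), body25.MID_HIP: (0, 100)}, n=60)
        events = GaitEvents(heel_strikes_left=[1.0], heel_strikes_right=[])
        out = trunk_inclination(track, events, offset_deg=12.0)
        assert out.iloc[0]["raw_deg"] == pytest.approx(0.0)
        assert out.iloc[0]["inclination_deg"] == pytest.approx(-12.0)

    def test_forward_lean_geometry(self):
        height = 100.0
        lean = np.tan(np.radians(20.0)) * height
        track = _leg_track({body25.NECK: (lean, 100 + height),
                            body25.MID_HIP: (0, 100)}, n=60)
        events = GaitEvents(heel_strikes_left=[1.0], heel_strikes_right=[])
        out = trunk_inclination(track, events, offset_deg=12.0)
        assert out.iloc[0]["raw_deg"] == pytest.approx(20.0)
        assert out.iloc[0]["inclination_deg"] == pytest.approx(8.0)

    def test_missing_keypoint_gives_nan(self):
        track = _leg_track({body25.NECK: (0, 200), body25.MID_HIP: (0, 100)}, n=60)
        track.xy[30, body25.NECK] = np.nan
        events = GaitEvents(heel_strikes_left=[1.0], heel_strikes_right=[])
        out = trunk_inclination(track, events)
        assert np.isnan(out.iloc[0]["raw_deg"])

    def test_commanded_lean_recovered(self):
        """A walker leaning 15° forward reads 3° after the 12° offset."""
        spec = vg.WalkerSpec(trunk_lean_deg=15.0)
        points, truth = vg.simulate_walk(spec)
        cam, setup = vg.sagittal_camera(spec, truth)
        track = vg.to_gait_coordinates(vg.project(points, cam, spec.fps), setup)
        from videogait.pipeline import analyze_sagittal_track

        res = analyze_sagittal_track(track, setup)
        steady = truth.steps[~truth.steps["transient"]]
        values = res.trunk[
            (res.trunk["time_s"] >= steady["t_start_s"].min())
            & (res.trunk["time_s"] <= steady["t_end_s"].max())
        ]["inclination_deg"].dropna()
        assert abs(values.mean() - 3.0) < 1.0
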