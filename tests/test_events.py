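"""Heel-strike/toe-off detection and cross-system event matching."""

import numpy as np
import pytest

import videogait as vg
from videogait import body25
from videogait.core import TrialKeypoints, Trajectory
from videogait.events import (
    GaitEvents,
    cross_reference_events,
    detect_events_frontal,
    detect_events_mocap,
    detect_events_sagittal,
)
from conftest import max_timing_error_frames


def _track_from_signals(signals=None, fps=30.0, n=300):
    """Minimal trial with chosen keypoint coordinate series set."""
    xy = np.zeros((n, body25.N_KEYPOINTS, 2))
    conf = np.ones((n, body25.N_KEYPOINTS))
    for (kp, axis), series in (signals or {}).items():
        xy[:, kp, axis] = series
    return TrialKeypoints(xy=xy, confidence=conf, fps=fps, view="test")


class TestSagittalDetector:
    def test_sinusoid_peaks_recovered(self):
        fps, f = 30.0, 0.9
        t = np.arange(300) / fps
        rel = 0.3 * np.sin(2 * np.pi * f * t)
        track = _track_from_signals({(body25.L_ANKLE, 0): rel,
                                     (body25.R_ANKLE, 0): -rel})
        events = detect_events_sagittal(track)
        expected = (np.arange(0.25 / f, t[-1], 1 / f))  # sine maxima
        for e in expected:
            assert np.min(np.abs(events.heel_strikes_left - e)) < 1 / fps
        # toe-offs at the minima
        expected_to = np.arange(0.75 / f, t[-1], 1 / f)
        for e in expected_to:
            assert np.min(np.abs(events.toe_offs_left - e)) < 1 / fps

    def test_constant_signal_no_events(self):
        track = _track_from_signals()
        events = detect_events_sagittal(track)
        assert events.heel_strikes_left.size == 0
        assert events.toe_offs_right.size == 0

    def test_simulator_heel_strikes_within_one_frame(self, sagittal_trial):
        from videogait.preprocess import lowpass_track

        track, setup, truth = sagittal_trial
        events = detect_events_sagittal(lowpass_track(track, 5.0))
        assert max_timing_error_frames(events, truth, setup.fps) <= 1.0

    def test_translation_invariance(self, sagittal_trial):
        from videogait.preprocess import lowpass_track

        track, _, _ = sagittal_trial
        shifted = track.copy()
        shifted.xy += np.array([123.0, -45.0])
        a = detect_events_sagittal(lowpass_track(track, 5.0))
        b = detect_events_sagittal(lowpass_track(shifted, 5.0))
        np.testing.assert_allclose(a.heel_strikes_left, b.heel_strikes_left)
        np.testing.assert_allclose(a.toe_offs_right, b.toe_offs_right)


class TestFrontalDetector:
    @staticmethod
    def _bump_signal(fps=30.0, n=90):
        """+A at t=1.0 s, −A at t=1.5 s (single bump pair)."""
        t = np.arange(n) / fps
        sig = 40 * np.exp(-((t - 1.0) / 0.08) ** 2) - 40 * np.exp(
            -((t - 1.5) / 0.08) ** 2
        )
        return _track_from_signals({(body25.L_ANKLE, 1): sig}, fps=fps, n=n)

    def test_away_side_rule(self):
        events = detect_events_frontal(self._bump_signal(), "away", smooth_hz=None)
        assert np.allclose(events.heel_strikes_left, [1.0], atol=0.05)
        assert np.allclose(events.heel_strikes_right, [1.5], atol=0.05)

    def test_toward_reverses_sides(self):
        events = detect_events_frontal(self._bump_signal(), "toward", smooth_hz=None)
        assert np.allclose(events.heel_strikes_right, [1.0], atol=0.05)
        assert np.allclose(events.heel_strikes_left, [1.5], atol=0.05)

    def test_direction_reversal_is_exact_label_swap(self, frontal_trial):
        track, _, _ = frontal_trial
        away = detect_events_frontal(track, "away")
        toward = detect_events_frontal(track, "toward")
        np.testing.assert_array_equal(away.heel_strikes_left, toward.heel_strikes_right)
        np.testing.assert_array_equal(away.heel_strikes_right, toward.heel_strikes_left)

    def test_simulator_heel_strikes_close_to_truth(self, frontal_trial):
        track, setup, truth = frontal_trial
        events = detect_events_frontal(track, setup.direction)
        assert max_timing_error_frames(events, truth, setup.fps) <= 2.0

    def test_missing_ankle_raises(self):
        track = _track_from_signals()
        track.xy[:, body25.L_ANKLE] = np.nan
        with pytest.raises(ValueError, match="left ankle"):
            detect_events_frontal(track, "away")

    def test_emits_heel_strikes_only(self, frontal_trial):
        track, setup, _ = frontal_trial
        events = detect_events_frontal(track, setup.direction)
        assert events.toe_offs_left.size == 0 and events.toe_offs_right.size == 0


class TestMocapDetector:
    def test_sinusoid_peaks(self):
        fps = 100.0
        t = np.arange(1000) / fps
        rel = 0.3 * np.sin(2 * np.pi * 0.9 * t)
        torso = Trajectory(np.zeros_like(t), fps)
        events = detect_events_mocap(
            Trajectory(rel, fps), Trajectory(-rel, fps), torso
        )
        expected = np.arange(0.25 / 0.9, t[-1], 1 / 0.9)
        for e in expected:
            assert np.min(np.abs(events.heel_strikes_left - e)) < 1 / fps

    def test_torso_equal_to_ankle_gives_no_events(self):
        fps = 100.0
        sig = np.sin(np.arange(500) / 20)
        traj = Trajectory(sig, fps)
        events = detect_events_mocap(traj, traj, Trajectory(sig.copy(), fps))
        assert events.heel_strikes_left.size == 0

    def test_simulator_markers_within_one_frame(self, default_walk):
        from videogait.preprocess import lowpass_zero_lag

        spec, points, truth = default_walk
        la = lowpass_zero_lag(Trajectory(points[:, body25.L_ANKLE, 0], spec.fps), 7.0)
        ra = lowpass_zero_lag(Trajectory(points[:, body25.R_ANKLE, 0], spec.fps), 7.0)
        torso = lowpass_zero_lag(Trajectory(points[:, body25.MID_HIP, 0], spec.fps), 7.0)
        events = detect_events_mocap(la, ra, torso)
        assert max_timing_error_frames(events, truth, spec.fps) <= 1.0


class TestCrossReference:
    def _events(self, left, right):
        return GaitEvents(heel_strikes_left=left, heel_strikes_right=right)

    def test_identical_lists_fully_matched(self):
        a = self._events([1.0, 2.0], [1.5, 2.5])
        matched = cross_reference_events(a, self._events([1.0, 2.0], [1.5, 2.5]), 0.25)
        assert matched.n_matched == 4
        assert matched.unmatched_a == [] and matched.unmatched_b == []

    def test_shift_within_tolerance_matched(self):
        a = self._events([1.0, 2.0], [1.5])
        b = self._events([1.125, 2.125], [1.625])
        matched = cross_reference_events(a, b, tol_s=0.25)
        assert matched.n_matched == 3

    def test_spurious_event_left_unmatched(self):
        a = self._events([1.0, 2.0], [])
        b = self._events([1.0, 1.4, 2.0], [])
        matched = cross_reference_events(a, b, tol_s=0.25)
        assert matched.n_matched == 2
        assert matched.unmatched_b == [(1.4, "left")]

    def test_empty_matching_allowed(self):
        matched = cross_reference_events(self._events([], []), self._events([1.0], []), 0.25)
        assert matched.n_matched == 0


def test_event_csv_roundtrip(tmp_path):
    events = GaitEvents(
        heel_strikes_left=[1.0, 2.1], heel_strikes_right=[1.55],
        toe_offs_left=[1.3], toe_offs_right=[0.9], source="sagittal",
    )
    path = tmp_path / "events.csv"
    events.to_csv(path)
    back = GaitEvents.from_csv(path)
    np.testing.assert_allclose(back.heel_strikes_left, events.heel_strikes_left)
    np.testing.assert_allclose(back.toe_offs_right, events.toe_offs_right)
    assert back.source == "sagittal"


def test_all_detectors_agree_on_steady_cycles(default_walk, frontal_trial, sagittal_trial):
    """On noiseless data the three detectors find the same steady strikes,
    with step times agreeing within a frame of ground truth."""
    from videogait.preprocess import lowpass_track, lowpass_zero_lag
    from conftest import steady_heel_strikes

    spec, points, truth = default_walk
    f_track, f_setup, _ = frontal_trial
    s_track, _, _ = sagittal_trial
    detectors = {
        "frontal": detect_events_frontal(f_track, f_setup.direction),
        "sagittal": detect_events_sagittal(lowpass_track(s_track, 5.0)),
        "mocap": detect_events_mocap(
            lowpass_zero_lag(Trajectory(points[:, body25.L_ANKLE, 0], spec.fps), 7.0),
            lowpass_zero_lag(Trajectory(points[:, body25.R_ANKLE, 0], spec.fps), 7.0),
            lowpass_zero_lag(Trajectory(points[:, body25.MID_HIP, 0], spec.fps), 7.0),
        ),
    }
    steady = steady_heel_strikes(truth)
    for name, events in detectors.items():
        for side, times in steady.items():
            detected = events.heel_strikes(side)
            for t in times:
                err = np.min(np.abs(detected - t)) * spec.fps
                assert err <= 2.0, f"{name} {side} strike at {t}: {err:.2f} frames"
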