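"""Torso pixel size, depth-change inversion, and frontal step parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import videogait as vg
from videogait import body25
from videogait.core import TrialKeypoints
from videogait.events import GaitEvents, detect_events_frontal
from videogait.frontal import (
    TorsoSizeSeries,
    default_reference_window,
    depth_change,
    evaluate_tracking_methods,
    frontal_step_table,
    infer_direction,
    size_ratio,
    torso_size_series,
)
from videogait.simulate import PinholeCamera


def _torso_track(neck, midhip, lsho=None, rsho=None, n=3):
    xy = np.full((n, body25.N_KEYPOINTS, 2), 0.0)
    conf = np.ones((n, body25.N_KEYPOINTS))
    xy[:, body25.NECK] = neck
    xy[:, body25.MID_HIP] = midhip
    xy[:, body25.L_SHOULDER] = lsho if lsho is not None else (0, 0)
    xy[:, body25.R_SHOULDER] = rsho if rsho is not None else (0, 0)
    return TrialKeypoints(xy=xy, confidence=conf, fps=30.0, view="frontal")


class TestTorsoSize:
    def test_height_is_vertical_neck_midhip_distance(self):
        track = _torso_track(neck=(0, 400), midhip=(0, 100))
        series = torso_size_series(track, "height")
        np.testing.assert_allclose(series.s_i, 300.0)

    def test_area_is_geometric_mean(self):
        track = _torso_track(
            neck=(0, 400), midhip=(0, 100), lsho=(73.5, 390), rsho=(-73.5, 390)
        )
        series = torso_size_series(track, "area")
        np.testing.assert_allclose(series.s_i, np.sqrt(300 * 147))

    def test_size_inversely_proportional_to_depth(self, default_walk):
        """Projected torso height × depth is constant (pinhole law)."""
        spec, points, truth = default_walk
        cam, setup = vg.frontal_camera(spec, truth)
        track = vg.project(points, cam, spec.fps)
        series = torso_size_series(track, "height")
        depth = cam.depth_of(points[:, body25.MID_HIP])
        product = series.s_i * depth
        assert np.nanstd(product) / np.nanmean(product) < 1e-3

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            torso_size_series(_torso_track((0, 1), (0, 0)), "volume")


class TestSizeRatio:
    def test_constant_series_ratio_one(self):
        series = TorsoSizeSeries(s_i=np.full(60, 210.0), fps=30.0, method="height")
        out = size_ratio(series, (0, 10), cutoff_hz=0)
        np.testing.assert_allclose(out.s_ratio, 1.0)
        assert out.s_ref == 210.0

    def test_halved_size_gives_half_ratio(self):
        s = np.concatenate([np.full(30, 210.0), np.full(30, 105.0)])
        out = size_ratio(TorsoSizeSeries(s_i=s, fps=30.0, method="height"), (0, 30),
                         cutoff_hz=0)
        np.testing.assert_allclose(out.s_ratio[40:], 0.5)

    def test_empty_reference_window_rejected(self):
        s = np.full(30, np.nan)
        s[20:] = 100.0
        with pytest.raises(ValueError, match="reference window"):
            size_ratio(TorsoSizeSeries(s_i=s, fps=30.0, method="height"), (0, 10))

    def test_filtered_ratio_tracks_pinhole_prediction(self, default_walk):
        """On a noiseless walking-away trial the filtered size ratio follows
        d_ref/(d_ref+Δd) with small RMS error."""
        spec, points, truth = default_walk
        cam, setup = vg.frontal_camera(spec, truth)
        track = vg.project(points, cam, spec.fps)
        series = torso_size_series(track, "height")
        events = GaitEvents(heel_strikes_left=truth.events.heel_strikes_left,
                            heel_strikes_right=truth.events.heel_strikes_right)
        window = default_reference_window(events, spec.fps, track.n_frames)
        out = size_ratio(series, window)
        predicted = setup.d_ref_m / (setup.d_ref_m + truth.delta_depth)
        rms = np.sqrt(np.nanmean((out.s_ratio - predicted) ** 2))
        assert rms < 0.02


class TestDepthChange:
    def test_reference_identity(self):
        series = TorsoSizeSeries(s_i=np.ones(5), fps=30.0, method="height",
                                 s_ref=1.0, s_ratio=np.ones(5))
        out = depth_change(series, d_ref=4.88)
        np.testing.assert_allclose(out.delta_d, 0.0)

    def test_half_ratio_doubles_depth(self):
        series = TorsoSizeSeries(s_i=np.ones(5), fps=30.0, method="height",
                                 s_ref=1.0, s_ratio=np.full(5, 0.5))
        out = depth_change(series, d_ref=4.88)
        np.testing.assert_allclose(out.delta_d, 4.88)

    def test_nonpositive_ratio_names_frame(self):
        series = TorsoSizeSeries(s_i=np.ones(3), fps=30.0, method="height",
                                 s_ref=1.0, s_ratio=np.array([1.0, -0.2, 1.0]))
        with pytest.raises(ValueError, match="frame 1"):
            depth_change(series, 4.88)

    def test_exact_inversion_over_validated_range(self):
        """Projecting a rigid subject at depth-changes up to 18.29 m from a
        4.88 m reference and inverting recovers the depth to 1e-6 m."""
        d_ref = 4.88
        cam = PinholeCamera(f_px=1400.0, position=np.zeros(3),
                            look=np.array([1.0, 0, 0]))
        dd = np.linspace(0.0, 18.29, 250)
        top = np.column_stack([d_ref + dd, np.full_like(dd, 1.4), np.zeros_like(dd)])
        bot = np.column_stack([d_ref + dd, np.full_like(dd, 0.9), np.zeros_like(dd)])
        size = np.abs(cam.project_points(top)[:, 1] - cam.project_points(bot)[:, 1])
        series = size_ratio(
            TorsoSizeSeries(s_i=size, fps=30.0, method="height"), (0, 1), cutoff_hz=0
        )
        out = depth_change(series, d_ref)
        assert np.max(np.abs(out.delta_d - dd)) < 1e-6


@settings(max_examples=50, deadline=None)
@given(st.floats(min_value=0.0, max_value=20.0),
       st.floats(min_value=500.0, max_value=3000.0),
       st.floats(min_value=0.5, max_value=2.2))
def test_depth_inversion_independent_of_focal_length_and_size(dd, f, subject_size):
    """Eq consistency: neither the focal length nor the subject's physical
    size enters the recovered depth-change."""
    d_ref = 4.88
    size_at = lambda d: f * subject_size / d
    ratio = size_at(d_ref + dd) / size_at(d_ref)
    recovered = d_ref / ratio - d_ref
    assert abs(recovered - dd) < 1e-9


class TestFrontalStepTable:
    def _depth(self, values, fps=30.0):
        from videogait.frontal import DepthSeries

        return DepthSeries(delta_d=np.asarray(values, float), fps=fps, d_ref=4.88)

    def test_step_definitions(self):
        fps = 30.0
        delta = np.zeros(90)
        delta[30:] = 1.0   # Δd at t=1.0 s
        delta[45:] = 1.6   # Δd at t=1.5 s
        events = GaitEvents(heel_strikes_left=[1.5], heel_strikes_right=[1.0])
        steps = frontal_step_table(self._depth(delta, fps), events)
        row = steps.iloc[0]
        assert row["side"] == "left"
        assert row["step_time_s"] == pytest.approx(0.5)
        assert row["step_length_m"] == pytest.approx(0.6)
        assert row["speed_mps"] == pytest.approx(1.2)

    def test_marching_in_place_zero_lengths(self):
        events = GaitEvents(heel_strikes_left=[1.0, 2.0], heel_strikes_right=[1.5, 2.5])
        steps = frontal_step_table(self._depth(np.zeros(120)), events)
        assert (steps["step_length_m"] == 0).all()

    def test_fewer_than_two_strikes_empty(self):
        events = GaitEvents(heel_strikes_left=[1.0], heel_strikes_right=[])
        steps = frontal_step_table(self._depth(np.zeros(60)), events)
        assert steps.empty

    def test_same_side_strikes_flagged_invalid(self):
        events = GaitEvents(heel_strikes_left=[1.0, 1.6], heel_strikes_right=[2.2])
        steps = frontal_step_table(self._depth(np.zeros(90)), events)
        assert list(steps["valid"]) == [False, True]

    def test_simulator_step_length_recovery(self, frontal_trial):
        from conftest import matched_steady_steps
        from videogait.pipeline import analyze_frontal_track

        track, setup, truth = frontal_trial
        res = analyze_frontal_track(track, setup, trim_steps=0)
        steps = matched_steady_steps(res.steps, res.events, truth)
        target = truth.steps[~truth.steps["transient"]]["torso_travel_m"].mean()
        assert abs(steps["step_length_m"].mean() - target) < 0.03


class TestDirectionInference:
    def test_shrinking_size_means_away(self):
        s = np.linspace(200, 100, 60)
        series = TorsoSizeSeries(s_i=s, fps=30.0, method="height")
        assert infer_direction(series) == "away"

    def test_growing_size_means_toward(self):
        s = np.linspace(100, 200, 60)
        series = TorsoSizeSeries(s_i=s, fps=30.0, method="height")
        assert infer_direction(series) == "toward"


class TestEvaluateTrackingMethods:
    def test_grid_ranks_and_orders(self, frontal_trial):
        track, setup, truth = frontal_trial
        events = detect_events_frontal(track, setup.direction)
        truth_steps = truth.steps.rename(columns={"torso_travel_m": "tt"})
        truth_tbl = truth.steps[["step_length_m"]].copy()
        ranking = evaluate_tracking_methods(
            track, events, truth_tbl, setup.d_ref_m,
            methods=("height", "width"), cutoffs_hz=(0.4, 1.0),
        )
        assert len(ranking) == 4
        mae = ranking["mean_abs_error_m"].to_numpy()
        assert (np.diff(mae) >= -1e-12).all()  # sorted ascending

    def test_single_cell_grid(self, frontal_trial):
        track, setup, truth = frontal_trial
        events = detect_events_frontal(track, setup.direction)
        ranking = evaluate_tracking_methods(
            track, events, truth.steps[["step_length_m"]], setup.d_ref_m,
            methods=("height",), cutoffs_hz=(0.4,),
        )
        assert len(ranking) == 1

    def test_empty_grid_rejected(self, frontal_trial):
        track, setup, truth = frontal_trial
        events = detect_events_frontal(track, setup.direction)
        with pytest.raises(ValueError, match="grid"):
            evaluate_tracking_methods(
                track, events, truth.steps[["step_length_m"]], setup.d_ref_m,
                methods=(), cutoffs_hz=(0.4,),
            )

    def test_tied_methods_keep_declaration_order(self, frontal_trial):
        track, setup, truth = frontal_trial
        events = detect_events_frontal(track, setup.direction)
        ranking = evaluate_tracking_methods(
            track, events, truth.steps[["step_length_m"]], setup.d_ref_m,
            methods=("height", "height"), cutoffs_hz=(0.4,),
        )
        assert len(ranking) == 2
        assert ranking.iloc[0]["mean_abs_error_m"] == ranking.iloc[1]["mean_abs_error_m"]
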