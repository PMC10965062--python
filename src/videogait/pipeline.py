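"""End-to-end analysis pipelines tying the modules together.

Each pipeline takes either a directory of OpenPose JSON files or an
already-tracked trial, runs preprocessing, event detection, and parameter
extraction, and returns a result object holding every intermediate stage so
callers can inspect or export any of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import body25
from .core import CameraSetup, TrialKeypoints
from .events import GaitEvents, detect_events_frontal, detect_events_sagittal
from .frontal import (
    DepthSeries,
    TorsoSizeSeries,
    default_reference_window,
    depth_change,
    frontal_step_table,
    infer_direction,
    size_ratio,
    torso_size_series,
)
from .io import read_openpose_frames, select_person, to_gait_coordinates
from .preprocess import (
    PreprocessConfig,
    SwapReport,
    correct_left_right,
    fill_gaps_track,
    lowpass_track,
)
from .sagittal import (
    JointAngleSeries,
    ScaleFactor,
    joint_angles,
    sagittal_step_table,
    scale_factor,
    trunk_inclination,
)

log = logging.getLogger("videogait")


def load_track(
    directory: str | Path,
    setup: CameraSetup,
    *,
    seed_frame: int | None = None,
    seed_point: tuple[float, float] | None = None,
    overrides: dict[int, int] | None = None,
) -> TrialKeypoints:
    """Read OpenPose JSON, pick and track the participant, and convert to
    gait coordinates.

    Without an explicit seed, the participant is seeded at the first frame
    with a detection, on the person with the highest mean confidence.
    """
    frames = read_openpose_frames(directory, setup.fps)
    if not frames:
        raise ValueError(f"no OpenPose JSON frames found in {directory}")
    if seed_frame is None:
        seed_frame = next((i for i, f in enumerate(frames) if f.n_persons), None)
        if seed_frame is None:
            raise ValueError("no person detected in any frame")
    if seed_point is None:
        dets = frames[seed_frame]
        best = max(range(dets.n_persons), key=lambda j: dets.persons[j][:, 2].mean())
        person = dets.persons[best]
        good = person[:, 2] > 0
        seed_point = tuple(person[good, :2].mean(axis=0))
    track, report = select_person(
        frames, seed_frame, seed_point, setup.fps, overrides=overrides
    )
    log.info(
        "tracked %d frames (%d missing, %d ambiguous)",
        track.n_frames, len(report.missing_frames), len(report.ambiguous_frames),
    )
    return to_gait_coordinates(track, setup)


def _trim_steps(steps: pd.DataFrame, trim: int) -> pd.DataFrame:
    """Drop the first and last ``trim`` valid steps (gait initiation and
    termination transients)."""
    if trim <= 0 or steps.empty:
        return steps
    valid_idx = steps.index[steps["valid"]]
    drop = list(valid_idx[:trim]) + list(valid_idx[-trim:] if trim <= len(valid_idx) else [])
    return steps.drop(index=set(drop))


@dataclass
class FrontalResult:
    track: TrialKeypoints
    swap_report: SwapReport
    events: GaitEvents
    size: TorsoSizeSeries
    depth: DepthSeries
    steps: pd.DataFrame
    direction: str


def analyze_frontal_track(
    track: TrialKeypoints,
    setup: CameraSetup,
    *,
    size_method: str = "height",
    config: PreprocessConfig | None = None,
    direction: str | None = None,
    ref_window: tuple[int, int] | None = None,
    trim_steps: int = 2,
    events: GaitEvents | None = None,
    interpolate_events: bool = False,
) -> FrontalResult:
    """Frontal-plane spatiotemporal analysis of a tracked trial.

    The trial must be in gait coordinates. Keypoint trajectories are
    swap-corrected and gap-filled; only the torso size-ratio series is
    low-pass filtered. ``events`` accepts externally supplied heel-strike
    times (e.g. from motion capture) in place of the frontal detector.
    Walking direction is auto-inferred from the size-ratio trend unless
    given. The first and last ``trim_steps`` steps are dropped as gait
    initiation/termination transients.
    """
    cfg = config or PreprocessConfig()
    track, swaps = correct_left_right(track)
    track = fill_gaps_track(track, cfg.max_gap_s)
    raw_size = torso_size_series(track, size_method)
    if direction is None:
        try:
            direction = infer_direction(raw_size)
        except ValueError:
            direction = setup.direction
    if events is None:
        events = detect_events_frontal(track, direction)
    if ref_window is None:
        ref_window = default_reference_window(events, track.fps, track.n_frames)
    size = size_ratio(raw_size, ref_window, cutoff_hz=cfg.cutoff_sizeratio_hz)
    depth = depth_change(size, setup.d_ref_m)
    steps = frontal_step_table(depth, events, interpolate=interpolate_events)
    steps = _trim_steps(steps, trim_steps)
    log.info(
        "frontal: %d swaps corrected, %d heel-strikes, %d steps",
        swaps.n_corrected,
        events.heel_strikes_left.size + events.heel_strikes_right.size,
        int(steps["valid"].sum()) if len(steps) else 0,
    )
    return FrontalResult(
        track=track, swap_report=swaps, events=events, size=size, depth=depth,
        steps=steps, direction=direction,
    )


def analyze_frontal(
    directory: str | Path, setup: CameraSetup, **kwargs
) -> FrontalResult:
    """Run the full frontal pipeline on a directory of OpenPose JSON."""
    track = load_track(directory, setup)
    return analyze_frontal_track(track, setup, **kwargs)


@dataclass
class SagittalResult:
    track: TrialKeypoints
    swap_report: SwapReport
    events: GaitEvents
    scale: ScaleFactor
    steps: pd.DataFrame
    angles: JointAngleSeries
    trunk: pd.DataFrame


def analyze_sagittal_track(
    track: TrialKeypoints,
    setup: CameraSetup,
    *,
    step_length_method: str = "ankle_distance",
    config: PreprocessConfig | None = None,
    trunk_offset_deg: float = 12.0,
    trim_steps: int = 2,
    events: GaitEvents | None = None,
) -> SagittalResult:
    """Sagittal-plane analysis: spatiotemporal parameters, joint kinematics
    and trunk inclination from a tracked trial in gait coordinates.

    Event detection and kinematics use the low-pass filtered trajectories;
    step positions are sampled from the gap-filled unfiltered trajectories
    at the (sub-frame) event times, since zero-phase smoothing clips
    trajectory extrema exactly where heel-strike positions are read.
    """
    cfg = config or PreprocessConfig()
    track, swaps = correct_left_right(track)
    filled = fill_gaps_track(track, cfg.max_gap_s)
    track = lowpass_track(filled, cfg.cutoff_sagittal_hz)
    scale = scale_factor(setup.calibration_distance_m, setup.calibration_distance_px)
    if events is None:
        events = detect_events_sagittal(track)
    steps = sagittal_step_table(filled, events, scale, step_length_method)
    steps = _trim_steps(steps, trim_steps)
    angles = joint_angles(track)
    trunk = trunk_inclination(track, events, trunk_offset_deg)
    log.info(
        "sagittal: %d swaps corrected, %d steps",
        swaps.n_corrected, int(steps["valid"].sum()) if len(steps) else 0,
    )
    return SagittalResult(
        track=track, swap_report=swaps, events=events, scale=scale, steps=steps,
        angles=angles, trunk=trunk,
    )


def analyze_sagittal(
    directory: str | Path, setup: CameraSetup, **kwargs
) -> SagittalResult:
    """Run the full sagittal pipeline on a directory of OpenPose JSON."""
    track = load_track(directory, setup)
    return analyze_sagittal_track(track, setup, **kwargs)
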