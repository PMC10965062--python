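"""Shared fixtures: pre-simulated walking trials and comparison helpers.

Simulations are session-scoped — the synthetic walker is deterministic, so
every test sees identical data and the suite stays fast.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings as _hypothesis_settings

import videogait as vg

_hypothesis_settings.register_profile("repro", derandomize=True)
_hypothesis_settings.load_profile("repro")
from videogait.events import GaitEvents
from videogait.io import to_gait_coordinates

warnings.filterwarnings("ignore", message="consecutive same-side heel-strikes")


@pytest.fixture(scope="session")
def default_walk():
    """Default symmetric walker: (spec, points3d, truth)."""
    spec = vg.WalkerSpec()
    points, truth = vg.simulate_walk(spec)
    return spec, points, truth


@pytest.fixture(scope="session")
def frontal_trial(default_walk):
    """Default walker seen by the frontal camera, in gait coordinates."""
    spec, points, truth = default_walk
    cam, setup = vg.frontal_camera(spec, truth)
    track = to_gait_coordinates(vg.project(points, cam, spec.fps), setup)
    return track, setup, truth


@pytest.fixture(scope="session")
def sagittal_trial(default_walk):
    """Default walker seen by the sagittal camera, in gait coordinates."""
    spec, points, truth = default_walk
    cam, setup = vg.sagittal_camera(spec, truth)
    track = to_gait_coordinates(vg.project(points, cam, spec.fps), setup)
    return track, setup, truth


def steady_heel_strikes(truth) -> dict[str, list[float]]:
    """Ground-truth heel-strike times of steady (non-transient) steps."""
    steady = truth.steps[~truth.steps["transient"]]
    out: dict[str, list[float]] = {"left": [], "right": []}
    for _, row in steady.iterrows():
        out[row["side"]].append(row["t_end_s"])
        other = "left" if row["side"] == "right" else "right"
        out[other].append(row["t_start_s"])
    return {side: sorted(set(times)) for side, times in out.items()}


def steady_truth_events(truth) -> GaitEvents:
    hs = steady_heel_strikes(truth)
    return GaitEvents(
        heel_strikes_left=hs["left"], heel_strikes_right=hs["right"], source="truth"
    )


def max_timing_error_frames(events: GaitEvents, truth, fps: float) -> float:
    """Worst |detected − true| heel-strike error (frames) over steady steps,
    matching each true strike to the nearest detected same-side event."""
    errs = []
    for side, times in steady_heel_strikes(truth).items():
        detected = events.heel_strikes(side)
        for t in times:
            if detected.size == 0:
                return np.inf
            errs.append(abs(detected[np.argmin(np.abs(detected - t))] - t) * fps)
    return max(errs) if errs else np.inf


def matched_steady_steps(steps, events: GaitEvents, truth, tol_s: float = 0.15):
    """Steps whose start and end heel-strikes both match ground-truth steady
    strikes — the matched-cycle comparison used throughout validation."""
    from videogait.events import cross_reference_events

    matched = cross_reference_events(events, steady_truth_events(truth), tol_s)
    times = sorted(p[0] for p in matched.pairs_left + matched.pairs_right)
    valid = steps[steps["valid"]]
    return valid[valid["t_start_s"].isin(times) & valid["t_end_s"].isin(times)]
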