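"""Frontal-plane analysis: monocular depth-change from torso pixel size and
the spatiotemporal gait parameters derived from it.

A pinhole camera maps a rigid segment of physical size ``s`` at depth ``d``
to a pixel size ``f·s/d``. Writing ``s_ratio = s_i / s_ref`` for the torso
pixel size relative to its value at a known reference depth ``d_ref``, the
pinhole model gives

    s_ratio = d_ref / (d_ref + Δd_i)

and therefore the depth-change of the walker relative to the start,

    Δd_i = d_ref / s_ratio − d_ref.

Neither the focal length nor the person's physical size appears: both cancel
in the ratio, so the pipeline runs with an uncalibrated camera. Step lengths
in the frontal view are distances travelled by the torso (in depth) between
consecutive bilateral heel-strikes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import body25
from .core import TrialKeypoints, Trajectory
from .events import GaitEvents
from .preprocess import lowpass_zero_lag

SIZE_METHODS = ("height", "width", "area")


@dataclass
class TorsoSizeSeries:
    """Torso pixel size per frame, optionally normalized by a reference."""

    s_i: np.ndarray          # px, NaN where missing
    fps: float
    method: str
    s_ref: float | None = None
    s_ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s_i = np.asarray(self.s_i, dtype=float)
        observed = self.s_i[np.isfinite(self.s_i)]
        if observed.size and (observed <= 0).any():
            raise ValueError("torso pixel size must be positive where observed")


@dataclass
class DepthSeries:
    """Depth-change (m) of the walker relative to the trial start."""

    delta_d: np.ndarray
    fps: float
    d_ref: float

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.delta_d.size) / self.fps

    def at_time(self, t: float, *, interpolate: bool = False) -> float:
        """Depth-change at time ``t`` (nearest frame, or linear sub-frame
        interpolation when ``interpolate`` is set)."""
        if interpolate:
            return float(np.interp(t, self.t, self.delta_d))
        i = int(round(t * self.fps))
        i = min(max(i, 0), self.delta_d.size - 1)
        return float(self.delta_d[i])


def torso_size_series(track: TrialKeypoints, method: str = "height") -> TorsoSizeSeries:
    """Per-frame torso pixel size.

    * ``height`` — vertical distance between neck and mid-hip keypoints;
    * ``width`` — horizontal distance between the shoulder keypoints;
    * ``area`` — sqrt(height × width), so that the size scales linearly
      with inverse depth like the one-dimensional measures.

    Frames where a required keypoint is missing beyond fillable gaps are NaN.
    """
    if method not in SIZE_METHODS:
        raise ValueError(f"method must be one of {SIZE_METHODS}, got {method!r}")
    height = np.abs(track.y(body25.NECK) - track.y(body25.MID_HIP))
    width = np.abs(track.x(body25.L_SHOULDER) - track.x(body25.R_SHOULDER))
    if method == "height":
        s = height
    elif method == "width":
        s = width
    else:
        s = np.sqrt(height * width)
    s = np.where(s > 0, s, np.nan)
    return TorsoSizeSeries(s_i=s, fps=track.fps, method=method)


def size_ratio(
    series: TorsoSizeSeries,
    ref_window: tuple[int, int],
    *,
    cutoff_hz: float = 0.4,
) -> TorsoSizeSeries:
    """Normalize the size series by its reference value and low-pass filter.

    ``s_ref`` is the median of the observed sizes over ``ref_window`` (frame
    range, end exclusive), which must lie in the epoch when the subject
    stands at the reference depth. The ratio series is filtered with a
    zero-lag Butterworth at ``cutoff_hz`` (0.4 Hz default, heavy smoothing
    that keeps the walking-depth ramp while rejecting within-step torso size
    fluctuation).
    """
    lo, hi = ref_window
    ref_vals = series.s_i[lo:hi]
    ref_vals = ref_vals[np.isfinite(ref_vals)]
    if ref_vals.size == 0:
        raise ValueError(f"reference window {ref_window} contains no observed sizes")
    s_ref = float(np.median(ref_vals))
    ratio = series.s_i / s_ref
    if cutoff_hz and cutoff_hz > 0:
        filt = lowpass_zero_lag(Trajectory(ratio, series.fps), cutoff_hz)
        ratio = filt.values
    return TorsoSizeSeries(
        s_i=series.s_i, fps=series.fps, method=series.method, s_ref=s_ref, s_ratio=ratio
    )


def default_reference_window(
    events: GaitEvents, fps: float, n_frames: int, *, margin_s: float = 0.3, min_frames: int = 5
) -> tuple[int, int]:
    """Frames from trial start until ``margin_s`` before the first
    heel-strike (at least ``min_frames``), the standing epoch at d_ref."""
    times, _ = events.merged_heel_strikes()
    if times.size:
        end = int((times[0] - margin_s) * fps)
    else:
        end = n_frames
    end = min(max(end, min_frames), n_frames)
    return 0, end


def depth_change(series: TorsoSizeSeries, d_ref: float) -> DepthSeries:
    """Invert the pinhole size ratio into a depth-change series:
    ``Δd_i = d_ref / s_ratio − d_ref``."""
    if series.s_ratio is None:
        raise ValueError("size series has no ratio: call size_ratio() first")
    if d_ref <= 0:
        raise ValueError("d_ref must be positive")
    ratio = np.asarray(series.s_ratio, dtype=float)
    bad = np.isfinite(ratio) & (ratio <= 0)
    if bad.any():
        raise ValueError(f"nonpositive size ratio at frame {int(np.argmax(bad))}")
    with np.errstate(invalid="ignore"):
        delta = d_ref / ratio - d_ref
    return DepthSeries(delta_d=delta, fps=series.fps, d_ref=d_ref)


def infer_direction(series: TorsoSizeSeries) -> str:
    """Infer walking direction from the trend of the size ratio: shrinking
    torso means walking away from the camera, growing means toward."""
    ratio = series.s_ratio if series.s_ratio is not None else series.s_i
    finite = np.flatnonzero(np.isfinite(ratio))
    if finite.size < 2:
        raise ValueError("size series too sparse to infer direction")
    return "away" if ratio[finite[-1]] < ratio[finite[0]] else "toward"


def frontal_step_table(
    depth: DepthSeries,
    events: GaitEvents,
    *,
    trial_id: str = "trial",
    condition: str = "preferred",
    interpolate: bool = False,
) -> pd.DataFrame:
    """Spatiotemporal step parameters from the frontal depth series.

    For each pair of consecutive bilateral heel-strikes: step time is the
    interval; step length is the absolute depth travelled by the torso; step
    speed is length/time. Each step is labeled by the side of its ending
    heel-strike (a left step ends at a left heel-strike). Consecutive
    same-side strikes yield rows flagged invalid. Fewer than two
    heel-strikes yield an empty table.
    """
    times, sides = events.merged_heel_strikes()
    rows = []
    for k in range(1, times.size):
        t0, t1 = float(times[k - 1]), float(times[k])
        valid = sides[k] != sides[k - 1]
        length = abs(depth.at_time(t1, interpolate=interpolate)
                     - depth.at_time(t0, interpolate=interpolate))
        dt = t1 - t0
        rows.append(
            {
                "trial_id": trial_id,
                "condition": condition,
                "side": str(sides[k]),
                "t_start_s": t0,
                "t_end_s": t1,
                "step_time_s": dt,
                "step_length_m": length,
                "speed_mps": length / dt if dt > 0 else np.nan,
                "method": "torso_travel",
                "valid": bool(valid),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id", "condition", "side", "t_start_s", "t_end_s",
            "step_time_s", "step_length_m", "speed_mps", "method", "valid",
        ],
    )


def evaluate_tracking_methods(
    track: TrialKeypoints,
    events: GaitEvents,
    truth: pd.DataFrame,
    d_ref: float,
    *,
    methods: Sequence[str] = SIZE_METHODS,
    cutoffs_hz: Sequence[float] = (0.2, 0.4, 0.6, 1.0, 2.0),
    ref_window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Grid evaluation of torso-size methods × smoothing cutoffs.

    For every combination the frontal pipeline is rerun and its step lengths
    compared with the ground-truth step table (column ``step_length_m``,
    matched by step order). Reports the mean absolute step-length error and
    the SD of the differences, sorted ascending by (error, SD); ties keep
    the declaration order of the grid.
    """
    if len(methods) == 0 or len(cutoffs_hz) == 0:
        raise ValueError("method/cutoff grid must be non-empty")
    if ref_window is None:
        ref_window = default_reference_window(events, track.fps, track.n_frames)
    truth_lengths = np.asarray(truth["step_length_m"], dtype=float)
    rows = []
    for order, (method, cutoff) in enumerate(
        [(m, c) for m in methods for c in cutoffs_hz]
    ):
        raw = torso_size_series(track, method)
        ratio = size_ratio(raw, ref_window, cutoff_hz=cutoff)
        depth = depth_change(ratio, d_ref)
        steps = frontal_step_table(depth, events)
        steps = steps[steps["valid"]]
        n = min(len(steps), truth_lengths.size)
        if n == 0:
            mae, sd = np.nan, np.nan
        else:
            diff = steps["step_length_m"].to_numpy()[:n] - truth_lengths[:n]
            mae = float(np.mean(np.abs(diff)))
            sd = float(np.std(diff, ddof=1)) if n > 1 else 0.0
        rows.append(
            {
                "method": method,
                "cutoff_hz": cutoff,
                "mean_abs_error_m": mae,
                "sd_diff_m": sd,
                "n_steps": n,
                "_order": order,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["mean_abs_error_m", "sd_diff_m", "_order"], kind="stable"
    ).drop(columns="_order").reset_index(drop=True)
    return table
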