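"""Sagittal-plane analysis: pixel-to-meter scaling, spatiotemporal step
parameters by two step-length definitions, lower-limb joint kinematics, and
trunk inclination.

Angle conventions (all in degrees, computed in gait coordinates with forward
positive and up positive):

* hip — angle of the thigh segment (hip→knee) from the downward vertical,
  flexion (knee forward of hip) positive;
* knee — angle between thigh and shank, 0 at full extension, flexion
  positive (hyperextension negative);
* ankle — angle between the shank (knee→ankle) and the foot (ankle→hallux)
  minus 90°, dorsiflexion positive;
* trunk inclination — angle from vertical of the mid-hip→neck segment at
  heel-strikes, forward lean positive, minus a fixed offset (12° default)
  that accounts for keypoints and markers tracking slightly different
  anatomical locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import body25
from .core import TrialKeypoints
from .events import GaitEvents


@dataclass
class ScaleFactor:
    """Pixel-to-meter conversion from a known distance along the line of
    progression."""

    meters_per_pixel: float

    def __post_init__(self) -> None:
        if self.meters_per_pixel <= 0:
            raise ValueError("meters_per_pixel must be positive")


def scale_factor(known_m: float, known_px: float) -> ScaleFactor:
    """Scale from a known physical distance and its pixel length, e.g. the
    distance between tape strips on the walkway."""
    if known_m <= 0 or known_px <= 0:
        raise ValueError("calibration distances must be positive")
    return ScaleFactor(meters_per_pixel=known_m / known_px)


def _value_at(track: TrialKeypoints, keypoint: int, t: float, axis: int) -> float:
    """Linear sub-frame interpolation of one keypoint coordinate (event
    times carry sub-frame precision)."""
    series = track.xy[:, keypoint, axis]
    return float(np.interp(t * track.fps, np.arange(track.n_frames), series))


def sagittal_step_table(
    track: TrialKeypoints,
    events: GaitEvents,
    scale: ScaleFactor,
    method: str = "ankle_distance",
    *,
    trial_id: str = "trial",
    condition: str = "preferred",
) -> pd.DataFrame:
    """Spatiotemporal step parameters from a preprocessed sagittal trial.

    Two step-length definitions are supported:

    * ``ankle_distance`` — horizontal distance between the two ankle
      keypoints at the instant of the ending heel-strike;
    * ``torso_travel`` — horizontal distance travelled by the mid-hip
      keypoint between the two heel-strikes (the definition shared with the
      frontal workflow).

    Steps are labeled by the side of the ending heel-strike; consecutive
    same-side strikes produce rows flagged invalid.
    """
    if method not in ("ankle_distance", "torso_travel"):
        raise ValueError(f"unknown step-length method {method!r}")
    times, sides = events.merged_heel_strikes()
    m = scale.meters_per_pixel
    rows = []
    for k in range(1, times.size):
        t0, t1 = float(times[k - 1]), float(times[k])
        if method == "ankle_distance":
            la = _value_at(track, body25.L_ANKLE, t1, 0)
            ra = _value_at(track, body25.R_ANKLE, t1, 0)
            length = abs(la - ra) * m
        else:
            length = abs(
                _value_at(track, body25.MID_HIP, t1, 0)
                - _value_at(track, body25.MID_HIP, t0, 0)
            ) * m
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
                "method": method,
                "valid": bool(sides[k] != sides[k - 1]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id", "condition", "side", "t_start_s", "t_end_s",
            "step_time_s", "step_length_m", "speed_mps", "method", "valid",
        ],
    )


@dataclass
class JointAngleSeries:
    """Hip, knee and ankle angle time series (degrees) per side."""

    hip_left: np.ndarray
    hip_right: np.ndarray
    knee_left: np.ndarray
    knee_right: np.ndarray
    ankle_left: np.ndarray
    ankle_right: np.ndarray
    fps: float

    def get(self, joint: str, side: str) -> np.ndarray:
        return getattr(self, f"{joint}_{side}")

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.hip_left.size) / self.fps
        return pd.DataFrame(
            {
                "time_s": t,
                "hip_left": self.hip_left,
                "hip_right": self.hip_right,
                "knee_left": self.knee_left,
                "knee_right": self.knee_right,
                "ankle_left": self.ankle_left,
                "ankle_right": self.ankle_right,
            }
        )


def _segment_angle_from_vertical(seg: np.ndarray) -> np.ndarray:
    """Signed angle (deg) of a downward-pointing segment from the downward
    vertical; positive when the distal end is forward of the proximal end."""
    return np.degrees(np.arctan2(seg[:, 0], -seg[:, 1]))


def joint_angles(track: TrialKeypoints) -> JointAngleSeries:
    """Sagittal lower-limb joint angles from keypoint triplets.

    Hip angles use the hip and knee keypoints; knee angles the hip, knee and
    ankle; ankle angles the knee, ankle and hallux. Frames with a missing
    keypoint yield NaN angle samples.
    """
    out: dict[str, np.ndarray] = {}
    for side, (hip_i, knee_i, ankle_i, toe_i) in (
        ("left", (body25.L_HIP, body25.L_KNEE, body25.L_ANKLE, body25.L_BIG_TOE)),
        ("right", (body25.R_HIP, body25.R_KNEE, body25.R_ANKLE, body25.R_BIG_TOE)),
    ):
        hip = track.xy[:, hip_i, :]
        knee = track.xy[:, knee_i, :]
        ankle = track.xy[:, ankle_i, :]
        toe = track.xy[:, toe_i, :]
        thigh = knee - hip
        shank = ankle - knee
        foot = toe - ankle
        with np.errstate(invalid="ignore"):
            thigh_ang = _segment_angle_from_vertical(thigh)
            shank_ang = _segment_angle_from_vertical(shank)
            out[f"hip_{side}"] = thigh_ang
            out[f"knee_{side}"] = thigh_ang - shank_ang
            # unsigned shank-foot angle minus 90: dorsiflexion positive
            cross = shank[:, 0] * foot[:, 1] - shank[:, 1] * foot[:, 0]
            dot = (shank * foot).sum(axis=1)
            out[f"ankle_{side}"] = np.degrees(np.arctan2(np.abs(cross), dot)) - 90.0
    return JointAngleSeries(fps=track.fps, **out)


def trunk_inclination(
    track: TrialKeypoints,
    events: GaitEvents,
    offset_deg: float = 12.0,
) -> pd.DataFrame:
    """Trunk inclination at each heel-strike, forward lean positive.

    Raw inclination is the angle from vertical of the mid-hip→neck segment;
    ``offset_deg`` is subtracted to align video keypoints with the
    marker-based definition. Heel-strikes at which neck or mid-hip is
    missing yield NaN.
    """
    times, sides = events.merged_heel_strikes()
    rows = []
    for t, side in zip(times, sides):
        i = int(round(float(t) * track.fps))
        i = min(max(i, 0), track.n_frames - 1)
        seg = track.xy[i, body25.NECK, :] - track.xy[i, body25.MID_HIP, :]
        if np.isfinite(seg).all():
            raw = float(np.degrees(np.arctan2(seg[0], seg[1])))
        else:
            raw = np.nan
        rows.append(
            {
                "time_s": float(t),
                "side": str(side),
                "raw_deg": raw,
                "inclination_deg": raw - offset_deg,
            }
        )
    return pd.DataFrame(rows, columns=["time_s", "side", "raw_deg", "inclination_deg"])
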