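"""Ground-truthed synthetic walking trials.

A kinematic 3D walker — prescribed trajectories, not locomotor dynamics —
is projected by an ideal pinhole camera into frontal or sagittal pixel
keypoints in the BODY_25 layout, optionally corrupted with Gaussian pixel
noise, dropout, and left/right label swaps, and written as OpenPose-format
JSON. Every trial carries its ground truth: heel-strike/toe-off times,
per-step lengths/times/speeds, the pelvis (depth) trajectory, and joint
angle curves, so measurement pipelines can be validated against known
answers.

World frame: x along the direction of travel, y up, z toward the walker's
left. The walker stands for a lead-in, walks with commanded per-side step
lengths and step times, and stands again after the last heel-strike.

Step length is the clinical definition — the horizontal ankle-to-ankle
distance at heel-strike. The trailing ankle rolls forward (heel-off) before
the contralateral heel-strike, so consecutive heel-contact points are spaced
``step_length + ankle_roll`` apart and the torso travels slightly farther
per step than the ankle-to-ankle distance, as observed with real walkers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import body25
from .core import CameraSetup, TrialKeypoints
from .events import GaitEvents
from .io import write_openpose_json  # noqa: F401  (re-exported: fixtures are written here)
from .sagittal import JointAngleSeries, _segment_angle_from_vertical


class InfeasibleSpecError(ValueError):
    """Commanded gait is impossible for the walker's segment lengths."""


@dataclass
class WalkerSpec:
    """Parameters of a synthetic walking trial.

    Per-side asymmetries follow the (left − right)/(left + right) index:
    ``step_length_asymmetry = 0.1`` commands left steps 10% of the summed
    step length longer than right steps. The seed fixes all randomness of
    the corruption model; the noiseless kinematics are deterministic.
    """

    stature_m: float = 1.75
    step_length_m: float = 0.65       # ankle-to-ankle distance at heel-strike
    step_time_s: float = 0.55
    step_length_asymmetry: float = 0.0
    step_time_asymmetry: float = 0.0
    trunk_lean_deg: float = 0.0       # forward lean of the mid-hip→neck segment
    duration_s: float = 7.5           # short walkway bout incl. lead-in/out
    lead_in_s: float = 1.5            # standing at the reference position
    lead_out_s: float = 1.0
    fps: float = 30.0
    start_x_m: float = 0.0
    first_side: str = "left"
    step_width_m: float = 0.12       # lateral distance between the feet
    ankle_roll_m: float = 0.05        # forward ankle shift at heel-off
    heel_drop_m: float = 0.004        # ankle settles by this after landing
    clearance_m: float = 0.03         # swing-foot lift above the skim height
    #: step-length scale of the gait initiation steps (and, mirrored, the
    #: termination steps): walkers accelerate over the first two steps
    initiation_scales: tuple[float, ...] = (0.45, 0.8)
    double_support_s: float = 0.10    # contralateral heel-strike → own toe-off
    landing_decel: float = 20.0       # heel-rocker deceleration (m/s^2)
    noise_px: float = 0.0
    dropout_p: float = 0.0
    swap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stature_m", "step_length_m", "step_time_s", "duration_s", "fps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.first_side not in ("left", "right"):
            raise ValueError("first_side must be 'left' or 'right'")
        for name in ("dropout_p", "swap_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        self.initiation_scales = tuple(self.initiation_scales)

    def step_length(self, side: str) -> float:
        a = self.step_length_asymmetry
        return self.step_length_m * (1 + a if side == "left" else 1 - a)

    def step_time(self, side: str) -> float:
        a = self.step_time_asymmetry
        return self.step_time_s * (1 + a if side == "left" else 1 - a)

    @classmethod
    def from_speed(
        cls,
        speed_mps: float,
        *,
        step_time_s: float = 0.55,
        walkway_m: float = 5.0,
        **kwargs,
    ) -> "WalkerSpec":
        """Spec whose steady-state torso (gait) speed equals ``speed_mps``.

        The torso advances ``step_length + ankle_roll`` per step, so the
        ankle-to-ankle step length is solved from the commanded speed. The
        bout covers a fixed walkway (slow walkers take longer, as in an
        overground protocol), so the camera range is speed-independent.
        """
        roll = kwargs.get("ankle_roll_m", cls.ankle_roll_m)
        a0 = kwargs.get("landing_decel", cls.landing_decel)
        # the torso advances step length + heel-off roll + heel-rocker travel
        step_length = speed_mps * step_time_s - roll - speed_mps**2 / (2 * a0)
        if step_length <= 0:
            raise ValueError("commanded speed too low for the given cadence")
        lead_in = kwargs.get("lead_in_s", cls.lead_in_s)
        lead_out = kwargs.get("lead_out_s", cls.lead_out_s)
        # capture volume: at least the walkway, stretched for fast walkers so
        # every bout lasts long enough for the slow size-ratio smoothing to
        # settle and contains plenty of steps
        distance = max(walkway_m, 7.0 * speed_mps)
        duration = kwargs.pop(
            "duration_s", lead_in + lead_out + distance / speed_mps
        )
        return cls(
            step_length_m=step_length,
            step_time_s=step_time_s,
            duration_s=duration,
            **kwargs,
        )

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WalkerSpec":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class Anthropometry:
    """Segment dimensions derived from stature (standard proportions)."""

    thigh: float
    shank: float
    ankle_h: float
    torso: float
    hip_half: float
    shoulder_half: float
    head: float
    foot_fwd: float
    foot_back: float

    @classmethod
    def from_stature(cls, s: float) -> "Anthropometry":
        return cls(
            thigh=0.245 * s,
            shank=0.246 * s,
            ankle_h=0.05 * s,
            torso=0.30 * s,
            hip_half=0.055 * s,
            shoulder_half=0.105 * s,
            head=0.115 * s,
            foot_fwd=0.085 * s,
            foot_back=0.035 * s,
        )

    @property
    def leg(self) -> float:
        return self.thigh + self.shank


@dataclass
class GroundTruth:
    """Everything the generator knows that a pipeline must recover."""

    events: GaitEvents
    steps: pd.DataFrame          # side, times, ankle step length, torso travel
    pelvis: np.ndarray           # (T, 3) world trajectory of the mid-hip
    angles: JointAngleSeries
    trunk_lean_deg: float
    fps: float
    gait_speed_mps: float        # steady-state torso speed
    spec: WalkerSpec

    @property
    def delta_depth(self) -> np.ndarray:
        """Forward torso displacement from the start (m); equals the
        depth-change seen by a frontal camera behind the walker."""
        return self.pelvis[:, 0] - self.pelvis[0, 0]


def _quintic(t: np.ndarray, t0: float, t1: float, p0: float, p1: float,
             v0: float = 0.0, v1: float = 0.0) -> np.ndarray:
    """Quintic trajectory with given end positions/velocities and zero end
    accelerations, evaluated at ``t`` (clipped to [t0, t1])."""
    T = t1 - t0
    tau = np.clip((t - t0) / T, 0.0, 1.0)
    V0, V1 = v0 * T, v1 * T
    # boundary conditions: p(0)=p0, p(1)=p1, p'(0)=V0, p'(1)=V1, p''=0 at ends
    D = p1 - p0
    a3 = 10 * D - 6 * V0 - 4 * V1
    a4 = -15 * D + 8 * V0 + 7 * V1
    a5 = 6 * D - 3 * V0 - 3 * V1
    return p0 + V0 * tau + a3 * tau**3 + a4 * tau**4 + a5 * tau**5


def _smoothstep(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    tau = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return tau * tau * (3 - 2 * tau)


def _ease_out(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Fast-start, gentle-finish ramp (quarter sine)."""
    tau = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return np.sin(0.5 * np.pi * tau)


def _schedule(spec: WalkerSpec) -> tuple[list[float], list[str], list[float]]:
    """Heel-strike times, sides, and per-step length scales (1 during steady
    gait, < 1 for initiation/termination)."""
    t_w0 = spec.lead_in_s
    t_end = spec.duration_s - spec.lead_out_s
    times: list[float] = []
    sides: list[str] = []
    side = spec.first_side
    t = t_w0
    while True:
        t_next = t + spec.step_time(side)
        if t_next > t_end:
            break
        times.append(t_next)
        sides.append(side)
        t = t_next
        side = "right" if side == "left" else "left"
    if len(times) < 3:
        raise ValueError("trial too short: fewer than 3 heel-strikes; increase duration")
    scales = [1.0] * len(times)
    for i, s in enumerate(spec.initiation_scales):
        if i < len(scales):
            scales[i] = min(scales[i], s)
        j = len(scales) - 1 - i
        if j >= 0:
            scales[j] = min(scales[j], s)
    return times, sides, scales


def _foot_positions(
    spec: WalkerSpec,
    sides: list[str],
    scales: list[float],
    speeds: list[float],
    a0: float,
) -> tuple[list[float], list[float]]:
    """Ankle contact and post-rocker rest positions for each strike, given
    the walking speed at each strike (the ankle crosses that speed at
    contact and decelerates at ``a0`` to rest)."""
    contacts: list[float] = []
    stops: list[float] = []
    trail_stop = spec.start_x_m
    for sd, sc, v in zip(sides, scales, speeds):
        contact = trail_stop + spec.ankle_roll_m + sc * spec.step_length(sd)
        contacts.append(contact)
        stops.append(contact + v**2 / (2 * a0))
        trail_stop = stops[-1]
    return contacts, stops


def _pelvis_spline(
    spec: WalkerSpec,
    hs_times: list[float],
    contacts: list[float],
    stops: list[float],
) -> PchipInterpolator:
    """Monotone spline through pelvis knots (midway between the ankles at
    each strike), flat during lead-in and lead-out."""
    x0 = spec.start_x_m
    roll = spec.ankle_roll_m
    knot_t = [0.0, spec.lead_in_s]
    knot_x = [x0, x0]
    for k, (tk, contact) in enumerate(zip(hs_times, contacts)):
        trail_rolled = (x0 if k == 0 else stops[k - 1]) + roll
        knot_t.append(tk)
        knot_x.append((contact + trail_rolled) / 2.0)
    knot_t.append(spec.duration_s + 1.0)
    knot_x.append(knot_x[-1])
    return PchipInterpolator(np.array(knot_t), np.array(knot_x))


def simulate_walk(spec: WalkerSpec) -> tuple[np.ndarray, GroundTruth]:
    """Generate 3D BODY_25 keypoint trajectories and their ground truth.

    Returns ``(points3d, truth)`` where ``points3d`` has shape
    ``(n_frames, 25, 3)`` in world meters. Raises
    :class:`InfeasibleSpecError` when the commanded step length cannot be
    reached with the walker's leg length.
    """
    anth = Anthropometry.from_stature(spec.stature_m)
    a0 = spec.landing_decel
    hs_times, hs_sides, hs_scales = _schedule(spec)
    n = int(round(spec.duration_s * spec.fps))
    t = np.arange(n) / spec.fps
    x0 = spec.start_x_m
    roll = spec.ankle_roll_m

    # ---- pelvis: two passes so the ankle crosses the *actual* pelvis speed
    # exactly at each contact (the relative-forward peak then sits at the
    # strike to sub-frame precision)
    v_est = [
        (roll + sc * spec.step_length(sd)) / spec.step_time(sd)
        for sd, sc in zip(hs_sides, hs_scales)
    ]
    contacts, stops = _foot_positions(spec, hs_sides, hs_scales, v_est, a0)
    pelvis_x_of = _pelvis_spline(spec, hs_times, contacts, stops)
    v_cross = [max(float(pelvis_x_of.derivative()(tk)), 0.05) for tk in hs_times]
    contacts, stops = _foot_positions(spec, hs_sides, hs_scales, v_cross, a0)
    pelvis_x_of = _pelvis_spline(spec, hs_times, contacts, stops)
    pelvis_vx_of = pelvis_x_of.derivative()
    v_cross = [max(float(pelvis_vx_of(tk)), 0.05) for tk in hs_times]
    pelvis_x = pelvis_x_of(t)

    # ---- feet ------------------------------------------------------------
    foot_z = {"left": spec.step_width_m / 2, "right": -spec.step_width_m / 2}
    ankle = {s: np.zeros((n, 3)) for s in ("left", "right")}
    planted = {s: np.ones(n, dtype=bool) for s in ("left", "right")}
    toe_off: dict[str, list[float]] = {"left": [], "right": []}

    roll_dur = 0.6 * spec.step_time_s  # slow heel-off: lift rate vanishes at
    settle_s = 0.08                    # the contralateral strike (smoothstep)
    roll_lift = 0.5 * roll
    push_delay = 0.5 / spec.fps        # push-off starts half a frame after
    push_lift = 0.005                  # the contralateral strike

    strike = {
        tk: (c, st, v, sc)
        for tk, c, st, v, sc in zip(hs_times, contacts, stops, v_cross, hs_scales)
    }

    for side in ("left", "right"):
        own = [(0.0, x0, x0, 0.0, 1.0)] + [
            (tk, *strike[tk]) for tk, s in zip(hs_times, hs_sides) if s == side
        ]
        ax = np.full(n, own[-1][2])
        ay = np.full(n, anth.ankle_h)
        for i, (ts, p_contact, p_stop, v_arr, sc_arr) in enumerate(own):
            t_next = own[i + 1][0] if i + 1 < len(own) else None
            if i == 0:
                ax[t >= ts] = p_stop  # quiet standing before the first swing
            if t_next is None:
                # terminal stance: still roll at the final contralateral
                # heel-strike, then lower the heel and stand
                contra = [tc for tc in hs_times if tc > ts]
                if contra:
                    tc = contra[0]
                    rs = max(tc - roll_dur, ts + v_arr / a0 + settle_s)
                    m = t >= rs
                    ax[m] = p_stop + roll * _smoothstep(t[m], rs, tc)
                    ay[m] = anth.ankle_h + roll_lift * (
                        _smoothstep(t[m], rs, tc)
                        - _smoothstep(t[m], tc, tc + 0.3)
                    )
                continue
            # contralateral heel-strike during this stance
            contra = [tc for tc in hs_times if ts < tc < t_next]
            if contra:
                tc = contra[0]
                t_to = tc + spec.double_support_s
                rs = max(tc - roll_dur, ts + v_arr / a0 + settle_s)
                # push-off begins just after the contralateral strike and
                # rolls the ankle forward over the forefoot faster than the
                # pelvis advances (quarter-sine: fast start, zero end rate)
                t_p0 = tc + push_delay
                v_c = strike[tc][2]
                push_roll = (v_c + 1.5) * (2 / np.pi) * (t_to - t_p0)
                m = t >= rs
                ax[m] = (
                    p_stop
                    + roll * _smoothstep(t[m], rs, tc)
                    + push_roll * _ease_out(t[m], t_p0, t_to)
                )
                ay[m] = (
                    anth.ankle_h
                    + roll_lift * _smoothstep(t[m], rs, tc)
                    + push_lift * _smoothstep(t[m], t_p0, t_to)
                )
                x_sw0 = p_stop + roll + push_roll
                y_sw0 = anth.ankle_h + roll_lift + push_lift
            else:
                # gait initiation: first swing starts from quiet standing
                t_to = ts if ts > 0 else spec.lead_in_s
                x_sw0, y_sw0 = p_stop, anth.ankle_h
            toe_off[side].append(t_to)
            # swing, then a heel-rocker landing: the ankle decelerates at a
            # constant rate, crossing the pelvis speed exactly at contact
            # (so the ankle-forward-of-pelvis curve peaks smoothly at the
            # strike) and rolling a few centimeters to rest just after
            m = t >= t_to
            planted[side][(t > t_to) & (t < t_next)] = False
            nxt_stop, nxt_v, nxt_sc = own[i + 1][2], own[i + 1][3], own[i + 1][4]
            t_stop = t_next + nxt_v / a0
            T_arc = nxt_v / a0 + 2.0 / spec.fps
            arc_start = t_stop - T_arc
            x_arc0 = nxt_stop - 0.5 * a0 * T_arc**2
            v0 = float(pelvis_vx_of(t_to))
            ax[m] = _quintic(t[m], t_to, arc_start, x_sw0, x_arc0, v0, a0 * T_arc)
            ma = t >= arc_start
            ax[ma] = nxt_stop - 0.5 * a0 * (t_stop - np.minimum(t[ma], t_stop)) ** 2
            # vertical: completes at 60% of swing: the foot skims just above
            # the ground through terminal swing, then settles after contact
            tau = np.clip((t[m] - t_to) / (t_next - t_to), 0.0, 1.0)
            tau_v = np.clip(tau / 0.6, 0.0, 1.0)
            lerp = y_sw0 + (anth.ankle_h + spec.heel_drop_m - y_sw0) * (
                tau_v * tau_v * (3 - 2 * tau_v)
            )
            # short initiation/termination steps are shuffles: low lift
            ay[m] = lerp + spec.clearance_m * nxt_sc * np.sin(np.pi * tau_v) ** 2
            ms = t >= t_next
            ay[ms] = anth.ankle_h + spec.heel_drop_m * np.clip(
                1 - (t[ms] - t_next) / settle_s, 0.0, 1.0
            )
        ankle[side][:, 0] = ax
        ankle[side][:, 1] = ay
        ankle[side][:, 2] = foot_z[side]

    # drop the bookkeeping toe-off of the initiating foot's pseudo-stance
    for side in ("left", "right"):
        toe_off[side] = [v for v in toe_off[side] if v > spec.lead_in_s - 1e-9]

    # ---- pelvis height: vault over the nearer planted support ------------
    l_eff = 0.96 * anth.leg
    dx_l = np.where(
        planted["left"], np.abs(pelvis_x - ankle["left"][:, 0]), np.inf
    )
    dx_r = np.where(
        planted["right"], np.abs(pelvis_x - ankle["right"][:, 0]), np.inf
    )
    dx_near = np.minimum(dx_l, dx_r)
    if not np.isfinite(dx_near).all():
        raise InfeasibleSpecError("flight phase: no planted foot at some frame")
    under = l_eff**2 - dx_near**2
    if (under <= 0).any():
        raise InfeasibleSpecError(
            "commanded step length exceeds what the leg geometry allows"
        )
    pelvis_y = anth.ankle_h + np.sqrt(under)
    pelvis = np.column_stack([pelvis_x, pelvis_y, np.zeros(n)])

    # ---- legs by two-link inverse kinematics ------------------------------
    def leg_ik(hip: np.ndarray, ank: np.ndarray) -> np.ndarray:
        d_vec = ank[:, :2] - hip[:, :2]
        d = np.hypot(d_vec[:, 0], d_vec[:, 1])
        if (d > anth.leg + 1e-9).any():
            worst = int(np.argmax(d))
            raise InfeasibleSpecError(
                f"leg extension exceeded: hip-ankle distance {d[worst]:.3f} m "
                f"> leg {anth.leg:.3f} m at t={worst / spec.fps:.3f} s"
            )
        d = np.minimum(d, anth.leg - 1e-12)
        cos_a = (anth.thigh**2 + d**2 - anth.shank**2) / (2 * anth.thigh * d)
        alpha = np.arccos(np.clip(cos_a, -1.0, 1.0))
        theta = np.arctan2(d_vec[:, 0], -d_vec[:, 1])  # from downward vertical
        # knee anterior to the hip-ankle line
        knee_ang = theta + alpha
        knee = hip.copy()
        knee[:, 0] += anth.thigh * np.sin(knee_ang)
        knee[:, 1] -= anth.thigh * np.cos(knee_ang)
        knee[:, 2] = ank[:, 2]
        return knee

    points = np.zeros((n, body25.N_KEYPOINTS, 3))
    lam = np.radians(spec.trunk_lean_deg)
    lean = np.array([np.sin(lam), np.cos(lam), 0.0])
    fwd = np.array([np.cos(lam), -np.sin(lam), 0.0])

    neck = pelvis + anth.torso * lean
    nose = neck + anth.head * lean + 0.03 * fwd
    points[:, body25.MID_HIP] = pelvis
    points[:, body25.NECK] = neck
    points[:, body25.NOSE] = nose
    for sign, eye, ear, shoulder, elbow, wrist in (
        (+1, body25.L_EYE, body25.L_EAR, body25.L_SHOULDER, body25.L_ELBOW, body25.L_WRIST),
        (-1, body25.R_EYE, body25.R_EAR, body25.R_SHOULDER, body25.R_ELBOW, body25.R_WRIST),
    ):
        z = np.array([0.0, 0.0, sign])
        points[:, eye] = nose + 0.032 * z - 0.01 * lean
        points[:, ear] = neck + anth.head * 0.9 * lean + 0.07 * z - 0.03 * fwd
        sh = neck + anth.shoulder_half * z - 0.02 * lean
        points[:, shoulder] = sh
        points[:, elbow] = sh - 0.19 * spec.stature_m * lean + 0.01 * fwd
        points[:, wrist] = sh - 0.34 * spec.stature_m * lean + 0.02 * fwd

    for side, hip_i, knee_i, ankle_i, toe_i, stoe_i, heel_i, sign in (
        ("left", body25.L_HIP, body25.L_KNEE, body25.L_ANKLE,
         body25.L_BIG_TOE, body25.L_SMALL_TOE, body25.L_HEEL, +1),
        ("right", body25.R_HIP, body25.R_KNEE, body25.R_ANKLE,
         body25.R_BIG_TOE, body25.R_SMALL_TOE, body25.R_HEEL, -1),
    ):
        hip = pelvis + np.array([0.0, 0.0, sign * anth.hip_half])
        hip[:, 2] = ankle[side][:, 2]  # leg moves in its own sagittal plane
        points[:, hip_i] = hip
        points[:, ankle_i] = ankle[side]
        points[:, knee_i] = leg_ik(hip, ankle[side])
        ground = anth.ankle_h - 0.01
        points[:, toe_i] = ankle[side] + np.array([anth.foot_fwd + 0.06, -ground, 0.0])
        points[:, stoe_i] = ankle[side] + np.array(
            [anth.foot_fwd + 0.035, -ground, -sign * 0.035]
        )
        points[:, heel_i] = ankle[side] + np.array([-anth.foot_back, -ground, 0.0])

    # ---- ground truth -----------------------------------------------------
    events = GaitEvents(
        heel_strikes_left=[tk for tk, s in zip(hs_times, hs_sides) if s == "left"],
        heel_strikes_right=[tk for tk, s in zip(hs_times, hs_sides) if s == "right"],
        toe_offs_left=toe_off["left"],
        toe_offs_right=toe_off["right"],
        source="truth",
    )
    rows = []
    for k in range(1, len(hs_times)):
        t0, t1 = hs_times[k - 1], hs_times[k]
        side = hs_sides[k]
        rows.append(
            {
                "side": side,
                "t_start_s": t0,
                "t_end_s": t1,
                "step_time_s": t1 - t0,
                "step_length_m": hs_scales[k] * spec.step_length(side),
                "torso_travel_m": float(pelvis_x_of(t1) - pelvis_x_of(t0)),
                "speed_mps": float(pelvis_x_of(t1) - pelvis_x_of(t0)) / (t1 - t0),
                "transient": hs_scales[k] < 1.0 or hs_scales[k - 1] < 1.0,
            }
        )
    steps = pd.DataFrame(rows)
    steady = steps[~steps["transient"]]
    gait_speed = float(steady["speed_mps"].mean()) if len(steady) else float(steps["speed_mps"].mean())

    angles = _angles_from_points(points, spec.fps)
    truth = GroundTruth(
        events=events,
        steps=steps,
        pelvis=pelvis,
        angles=angles,
        trunk_lean_deg=spec.trunk_lean_deg,
        fps=spec.fps,
        gait_speed_mps=gait_speed,
        spec=spec,
    )
    return points, truth


def _angles_from_points(points: np.ndarray, fps: float) -> JointAngleSeries:
    """Ground-truth joint angles from world coordinates, using the same
    conventions as the video pipeline (sagittal x-y plane)."""
    out = {}
    for side, (hip_i, knee_i, ankle_i, toe_i) in (
        ("left", (body25.L_HIP, body25.L_KNEE, body25.L_ANKLE, body25.L_BIG_TOE)),
        ("right", (body25.R_HIP, body25.R_KNEE, body25.R_ANKLE, body25.R_BIG_TOE)),
    ):
        thigh = (points[:, knee_i] - points[:, hip_i])[:, :2]
        shank = (points[:, ankle_i] - points[:, knee_i])[:, :2]
        foot = (points[:, toe_i] - points[:, ankle_i])[:, :2]
        thigh_ang = _segment_angle_from_vertical(thigh)
        shank_ang = _segment_angle_from_vertical(shank)
        out[f"hip_{side}"] = thigh_ang
        out[f"knee_{side}"] = thigh_ang - shank_ang
        cross = shank[:, 0] * foot[:, 1] - shank[:, 1] * foot[:, 0]
        dot = (shank * foot).sum(axis=1)
        out[f"ankle_{side}"] = np.degrees(np.arctan2(np.abs(cross), dot)) - 90.0
    return JointAngleSeries(fps=fps, **out)


# --------------------------------------------------------------------------
# Pinhole projection


@dataclass
class PinholeCamera:
    """Ideal pinhole camera with no lens distortion.

    ``look`` is the optical axis as a world unit vector along ±x (frontal)
    or ±z (sagittal); up is world +y. A rigid segment of physical size s at
    depth d projects to pixel size f·s/d. Image coordinates are raw pixels:
    origin top-left, y downward.
    """

    f_px: float
    position: np.ndarray
    look: np.ndarray
    image_size: tuple[int, int] = (1920, 1080)
    principal: tuple[float, float] | None = None
    orientation: str = "frontal"

    def __post_init__(self) -> None:
        if self.f_px <= 0:
            raise ValueError("focal length must be positive")
        self.position = np.asarray(self.position, dtype=float)
        self.look = np.asarray(self.look, dtype=float)
        self.look = self.look / np.linalg.norm(self.look)
        if self.principal is None:
            self.principal = (self.image_size[0] / 2.0, self.image_size[1] / 2.0)
        up = np.array([0.0, 1.0, 0.0])
        self.right = np.cross(up, self.look)
        nrm = np.linalg.norm(self.right)
        if nrm < 1e-9:
            raise ValueError("optical axis may not be vertical")
        self.right /= nrm

    def project_points(self, points: np.ndarray) -> np.ndarray:
        """Project world points (..., 3) to raw image pixels (..., 2)."""
        rel = points - self.position
        depth = rel @ self.look
        if (depth <= 0.05).any():
            raise ValueError("point at or behind the camera plane")
        u = self.principal[0] + self.f_px * (rel @ self.right) / depth
        up = np.array([0.0, 1.0, 0.0])
        v = self.principal[1] - self.f_px * (rel @ up) / depth
        return np.stack([u, v], axis=-1)

    def depth_of(self, points: np.ndarray) -> np.ndarray:
        return (points - self.position) @ self.look


def project(points3d: np.ndarray, camera: PinholeCamera, fps: float) -> TrialKeypoints:
    """Project (n_frames, 25, 3) world trajectories into a raw-pixel trial
    with unit confidence everywhere."""
    xy = camera.project_points(points3d)
    conf = np.ones(points3d.shape[:2])
    return TrialKeypoints(xy=xy, confidence=conf, fps=fps, view="raw")


def frontal_camera(
    spec: WalkerSpec,
    truth: GroundTruth,
    *,
    toward: bool = False,
    offset_m: float = 1.52,
    height_m: float = 1.0,
    f_px: float = 1400.0,
    image_size: tuple[int, int] = (1920, 1080),
) -> tuple[PinholeCamera, CameraSetup]:
    """Frontal camera ``offset_m`` behind the start (walking away) or beyond
    the end of the walk (walking toward), with the matching CameraSetup."""
    x_start = truth.pelvis[0, 0]
    if toward:
        x_cam = float(truth.pelvis[:, 0].max()) + offset_m
        look = np.array([-1.0, 0.0, 0.0])
        d_ref = x_cam - x_start
        direction = "toward"
    else:
        x_cam = x_start - offset_m
        look = np.array([1.0, 0.0, 0.0])
        d_ref = x_start - x_cam
        direction = "away"
    cam = PinholeCamera(
        f_px=f_px,
        position=np.array([x_cam, height_m, 0.0]),
        look=look,
        image_size=image_size,
        orientation="frontal",
    )
    setup = CameraSetup(
        view="frontal", direction=direction, fps=spec.fps, d_ref_m=d_ref,
        image_size=image_size,
    )
    return cam, setup


def sagittal_camera(
    spec: WalkerSpec,
    truth: GroundTruth,
    *,
    distance_m: float = 6.0,
    height_m: float = 1.0,
    f_px: float = 1400.0,
    image_size: tuple[int, int] = (1920, 1080),
    from_left: bool = False,
    calibration_distance_m: float = 4.83,
) -> tuple[PinholeCamera, CameraSetup]:
    """Sagittal camera to the walker's side, aimed at the middle of the
    steady-state measurement volume, with a CameraSetup whose pixel
    calibration matches tape strips on the walkway (at the walker's plane of
    progression)."""
    steady = truth.steps[~truth.steps["transient"]]
    if len(steady):
        i0 = int(float(steady["t_start_s"].min()) * truth.fps)
        i1 = int(float(steady["t_end_s"].max()) * truth.fps)
        x_mid = float((truth.pelvis[i0, 0] + truth.pelvis[i1, 0]) / 2.0)
    else:
        x_mid = float((truth.pelvis[0, 0] + truth.pelvis[:, 0].max()) / 2.0)
    if from_left:
        # camera on the walker's left, looking right: subject travels image-left
        z_cam, look, direction = distance_m, np.array([0.0, 0.0, -1.0]), "left-facing"
    else:
        z_cam, look, direction = -distance_m, np.array([0.0, 0.0, 1.0]), "right-facing"
    cam = PinholeCamera(
        f_px=f_px,
        position=np.array([x_mid, height_m, z_cam]),
        look=look,
        image_size=image_size,
        orientation="sagittal",
    )
    calibration_px = f_px * calibration_distance_m / distance_m
    setup = CameraSetup(
        view="sagittal", direction=direction, fps=spec.fps,
        calibration_distance_m=calibration_distance_m,
        calibration_distance_px=calibration_px,
        image_size=image_size,
    )
    return cam, setup


# --------------------------------------------------------------------------
# Corruption model


@dataclass
class CorruptionLog:
    """Record of injected degradations, for validating their correction."""

    swapped_frames: list[int] = field(default_factory=list)
    dropped: list[tuple[int, int]] = field(default_factory=list)  # (frame, keypoint)


def corrupt(
    track: TrialKeypoints,
    sigma_px: float = 0.0,
    dropout_p: float = 0.0,
    swap_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    *,
    swap_block_length: int = 1,
) -> tuple[TrialKeypoints, CorruptionLog]:
    """Degrade a projected trial with the failure modes of pose estimation.

    Additive Gaussian pixel noise (``sigma_px``); keypoints dropped to
    confidence 0 with probability ``dropout_p``; lower-limb left/right
    labels exchanged on randomly chosen frames at ``swap_rate`` (in blocks
    of ``swap_block_length`` consecutive frames). All randomness is driven
    by ``seed``; the injection log is reproducible bit-exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = track.copy()
    log = CorruptionLog()
    n = out.n_frames
    if sigma_px > 0:
        out.xy = out.xy + rng.normal(0.0, sigma_px, size=out.xy.shape)
    if dropout_p > 0:
        drop = rng.random((n, body25.N_KEYPOINTS)) < dropout_p
        out.xy[drop] = np.nan
        out.confidence[drop] = 0.0
        log.dropped = [tuple(ij) for ij in np.argwhere(drop)]
    if swap_rate > 0:
        starts = np.flatnonzero(rng.random(n) < swap_rate / max(swap_block_length, 1))
        swapped: set[int] = set()
        for s in starts:
            swapped.update(range(s, min(s + swap_block_length, n)))
        pair_idx = np.array(body25.LOWER_LIMB_PAIRS)
        li, ri = pair_idx[:, 0], pair_idx[:, 1]
        for i in sorted(swapped):
            out.xy[i, li], out.xy[i, ri] = out.xy[i, ri].copy(), out.xy[i, li].copy()
            out.confidence[i, li], out.confidence[i, ri] = (
                out.confidence[i, ri].copy(),
                out.confidence[i, li].copy(),
            )
        log.swapped_frames = sorted(swapped)
    return out, log


def write_ground_truth(truth: GroundTruth, directory: str | Path) -> None:
    """Write ground-truth CSVs (events, steps, depth, angles) next to a
    simulated trial's JSON files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.events.to_csv(directory / "truth_events.csv")
    truth.steps.to_csv(directory / "truth_steps.csv", index=False)
    pd.DataFrame(
        {
            "time_s": np.arange(truth.pelvis.shape[0]) / truth.fps,
            "delta_depth_m": truth.delta_depth,
        }
    ).to_csv(directory / "truth_depth.csv", index=False)
    truth.angles.to_frame().to_csv(directory / "truth_angles.csv", index=False)
    with open(directory / "truth_meta.json", "w") as fh:
        json.dump(
            {
                "gait_speed_mps": truth.gait_speed_mps,
                "trunk_lean_deg": truth.trunk_lean_deg,
                "fps": truth.fps,
            },
            fh,
        )
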