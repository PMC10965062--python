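"""Gait-event detection from sagittal keypoints, frontal keypoints, or
motion-capture markers, and cross-referencing of events between systems.

Heel-strikes and toe-offs are detected as extrema of relative trajectories:

* sagittal video — positive/negative peaks of the horizontal ankle
  trajectory relative to the mid-hip keypoint (per side);
* frontal video — extrema of the vertical distance between the left and
  right ankle keypoints; walking away from the camera, positive peaks are
  left heel-strikes and negative peaks right heel-strikes (reversed when
  walking toward the camera); the frontal detector emits heel-strikes only;
* motion capture — positive/negative peaks of the anterior-posterior ankle
  marker trajectory relative to the torso (per side).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from . import body25
from .core import TrialKeypoints, Trajectory


@dataclass
class GaitEvents:
    """Heel-strike and toe-off times (s) per side from one source."""

    heel_strikes_left: np.ndarray
    heel_strikes_right: np.ndarray
    toe_offs_left: np.ndarray = field(default_factory=lambda: np.array([]))
    toe_offs_right: np.ndarray = field(default_factory=lambda: np.array([]))
    source: str = "unknown"

    def __post_init__(self) -> None:
        for name in ("heel_strikes_left", "heel_strikes_right",
                     "toe_offs_left", "toe_offs_right"):
            arr = np.sort(np.asarray(getattr(self, name), dtype=float))
            setattr(self, name, arr)
            if arr.size > 1 and not (np.diff(arr) > 0).all():
                raise ValueError(f"{name}: event times must be strictly increasing")

    def heel_strikes(self, side: str) -> np.ndarray:
        return self.heel_strikes_left if side == "left" else self.heel_strikes_right

    def merged_heel_strikes(self) -> tuple[np.ndarray, np.ndarray]:
        """All heel-strikes in time order with side labels.

        Returns ``(times, sides)``; sides is an array of "left"/"right".
        Consecutive same-side strikes are kept (downstream step building
        flags them), but a warning is raised since alternation is expected.
        """
        times = np.concatenate([self.heel_strikes_left, self.heel_strikes_right])
        sides = np.array(
            ["left"] * self.heel_strikes_left.size + ["right"] * self.heel_strikes_right.size
        )
        order = np.argsort(times)
        times, sides = times[order], sides[order]
        if times.size > 1 and (sides[1:] == sides[:-1]).any():
            warnings.warn("consecutive same-side heel-strikes detected", stacklevel=2)
        return times, sides

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "side", "event_type", "source"])
            for side in ("left", "right"):
                for t in self.heel_strikes(side):
                    w.writerow([f"{t:.6f}", side, "heel_strike", self.source])
            for side, arr in (("left", self.toe_offs_left), ("right", self.toe_offs_right)):
                for t in arr:
                    w.writerow([f"{t:.6f}", side, "toe_off", self.source])

    @classmethod
    def from_csv(cls, path: str | Path) -> "GaitEvents":
        rows: dict[tuple[str, str], list[float]] = {}
        source = "unknown"
        with open(path) as fh:
            for row in csv.DictReader(fh):
                rows.setdefault((row["side"], row["event_type"]), []).append(
                    float(row["time_s"])
                )
                source = row.get("source", source)
        return cls(
            heel_strikes_left=rows.get(("left", "heel_strike"), []),
            heel_strikes_right=rows.get(("right", "heel_strike"), []),
            toe_offs_left=rows.get(("left", "toe_off"), []),
            toe_offs_right=rows.get(("right", "toe_off"), []),
            source=source,
        )


@dataclass
class MatchedCycles:
    """Pairing of heel-strikes between two sources on a common clock."""

    pairs_left: list[tuple[float, float]]
    pairs_right: list[tuple[float, float]]
    unmatched_a: list[tuple[float, str]]
    unmatched_b: list[tuple[float, str]]

    @property
    def n_matched(self) -> int:
        return len(self.pairs_left) + len(self.pairs_right)


def _peak_params(signal: np.ndarray, fps: float) -> tuple[float, float]:
    """Scale-free peak-detection parameters for a quasi-periodic signal.

    Minimum separation is 0.4× the interval between same-sign extrema
    implied by the dominant frequency (one stride period for gait signals);
    minimum prominence is 20% of the interquartile range. A flat signal
    (IQR 0) yields no detectable peaks.
    """
    finite = signal[np.isfinite(signal)]
    if finite.size < 4:
        return 1.0, np.inf
    q75, q25 = np.percentile(finite, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return 1.0, np.inf
    x = signal.copy()
    x[~np.isfinite(x)] = np.nanmean(finite)
    x = x - x.mean()
    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fps)
    # locate the stride frequency: ignore DC, drift and the bout envelope
    # (whose fundamental scales with 1/duration) below the gait band
    valid = freqs >= max(0.35, 3.0 * fps / x.size)
    if not valid.any() or spectrum[valid].max() == 0:
        distance = 1.0
    else:
        f_dom = freqs[valid][np.argmax(spectrum[valid])]
        distance = max(1.0, 0.4 * fps / f_dom)
    return distance, 0.2 * iqr


def _refine_peaks(x: np.ndarray, idx: np.ndarray, fps: float) -> np.ndarray:
    """Sub-frame peak times by parabolic interpolation through the sample
    maximum and its neighbours (offset clamped to ±½ frame)."""
    times = []
    for p in idx:
        off = 0.0
        if 0 < p < x.size - 1:
            denom = x[p - 1] - 2 * x[p] + x[p + 1]
            if denom < 0:
                off = float(np.clip(0.5 * (x[p - 1] - x[p + 1]) / denom, -0.5, 0.5))
        times.append((p + off) / fps)
    return np.asarray(times)


def _detect_peaks(signal: np.ndarray, fps: float) -> tuple[np.ndarray, np.ndarray]:
    """Positive and negative peak times (s) of a relative trajectory."""
    if signal.size < 5 or not np.isfinite(signal).any():
        warnings.warn("signal too short for event detection", stacklevel=3)
        return np.array([]), np.array([])
    distance, prominence = _peak_params(signal, fps)
    if not np.isfinite(prominence):
        return np.array([]), np.array([])
    x = signal.copy()
    bad = ~np.isfinite(x)
    if bad.all():
        return np.array([]), np.array([])
    if bad.any():
        idx = np.arange(x.size)
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    pos, _ = find_peaks(x, distance=distance, prominence=prominence)
    neg, _ = find_peaks(-x, distance=distance, prominence=prominence)
    return _refine_peaks(x, pos, fps), _refine_peaks(-x, neg, fps)


def detect_events_sagittal(track: TrialKeypoints) -> GaitEvents:
    """Heel-strikes and toe-offs from a preprocessed sagittal-view trial.

    Per side, heel-strikes at positive peaks and toe-offs at negative peaks
    of the horizontal ankle trajectory relative to the mid-hip keypoint
    (forward positive in gait coordinates).
    """
    hip_x = track.x(body25.MID_HIP)
    out = {}
    for side, ankle in (("left", body25.L_ANKLE), ("right", body25.R_ANKLE)):
        rel = track.x(ankle) - hip_x
        hs, to = _detect_peaks(rel, track.fps)
        out[side] = (hs, to)
    return GaitEvents(
        heel_strikes_left=out["left"][0],
        heel_strikes_right=out["right"][0],
        toe_offs_left=out["left"][1],
        toe_offs_right=out["right"][1],
        source="sagittal",
    )


def detect_events_frontal(
    track: TrialKeypoints, direction: str, *, smooth_hz: float | None = 6.0
) -> GaitEvents:
    """Heel-strikes from a preprocessed frontal-view trial.

    Events at extrema of the vertical distance between the left and right
    ankle keypoints. Walking away: positive peaks are left heel-strikes,
    negative peaks right heel-strikes; the mapping reverses walking toward
    the camera. Only heel-strikes are emitted. The difference signal is
    zero-lag low-pass filtered at ``smooth_hz`` before peak picking (the
    gait content lies below ~2 Hz; this suppresses pixel noise on the
    small far-range peaks without moving the extrema).
    """
    if direction not in ("away", "toward"):
        raise ValueError(f"direction must be away/toward, got {direction!r}")
    left_y = track.y(body25.L_ANKLE)
    right_y = track.y(body25.R_ANKLE)
    for name, y in (("left", left_y), ("right", right_y)):
        if not np.isfinite(y).any():
            raise ValueError(f"{name} ankle missing throughout the trial")
    signal = left_y - right_y
    if smooth_hz:
        from .preprocess import lowpass_zero_lag
        from .core import Trajectory

        finite = np.isfinite(signal)
        filled = signal.copy()
        if not finite.all() and finite.any():
            idx = np.arange(signal.size)
            filled[~finite] = np.interp(idx[~finite], idx[finite], signal[finite])
        signal = lowpass_zero_lag(Trajectory(filled, track.fps), smooth_hz).values
    pos, neg = _detect_peaks(signal, track.fps)
    if direction == "away":
        left_hs, right_hs = pos, neg
    else:
        left_hs, right_hs = neg, pos
    return GaitEvents(
        heel_strikes_left=left_hs, heel_strikes_right=right_hs, source="frontal"
    )


def detect_events_mocap(
    ankle_ap_left: Trajectory, ankle_ap_right: Trajectory, torso_ap: Trajectory
) -> GaitEvents:
    """Heel-strikes and toe-offs from anterior-posterior marker trajectories.

    Per side, heel-strikes at positive and toe-offs at negative peaks of the
    ankle marker relative to the torso. Trajectories should be filtered at
    the marker-data cutoff first.
    """
    out = {}
    for side, ankle in (("left", ankle_ap_left), ("right", ankle_ap_right)):
        if len(ankle) != len(torso_ap):
            raise ValueError("ankle and torso trajectories must share length")
        rel = ankle.values - torso_ap.values
        hs, to = _detect_peaks(rel, ankle.fps)
        out[side] = (hs, to)
    return GaitEvents(
        heel_strikes_left=out["left"][0],
        heel_strikes_right=out["right"][0],
        toe_offs_left=out["left"][1],
        toe_offs_right=out["right"][1],
        source="mocap",
    )


def _greedy_match(
    a: np.ndarray, b: np.ndarray, tol_s: float
) -> tuple[list[tuple[float, float]], list[float], list[float]]:
    """Greedy nearest-time matching, each event in at most one pair."""
    pairs: list[tuple[float, float]] = []
    if a.size and b.size:
        cands = [(abs(ta - tb), i, j) for i, ta in enumerate(a) for j, tb in enumerate(b)
                 if abs(ta - tb) <= tol_s + 1e-12]
        cands.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _, i, j in cands:
            if i not in used_a and j not in used_b:
                pairs.append((float(a[i]), float(b[j])))
                used_a.add(i)
                used_b.add(j)
        pairs.sort()
    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    un_a = [float(t) for t in a if float(t) not in matched_a]
    un_b = [float(t) for t in b if float(t) not in matched_b]
    return pairs, un_a, un_b


def cross_reference_events(
    a: GaitEvents, b: GaitEvents, tol_s: float = 0.25
) -> MatchedCycles:
    """Match same-side heel-strikes between two sources within ``tol_s``.

    Both event sets must come from the same walking bout on a common clock.
    Gait cycles for between-system comparison are built only from matched
    consecutive events; unmatched events take part in no comparison.
    """
    pairs_l, un_a_l, un_b_l = _greedy_match(
        a.heel_strikes_left, b.heel_strikes_left, tol_s
    )
    pairs_r, un_a_r, un_b_r = _greedy_match(
        a.heel_strikes_right, b.heel_strikes_right, tol_s
    )
    return MatchedCycles(
        pairs_left=pairs_l,
        pairs_right=pairs_r,
        unmatched_a=[(t, "left") for t in un_a_l] + [(t, "right") for t in un_a_r],
        unmatched_b=[(t, "left") for t in un_b_l] + [(t, "right") for t in un_b_r],
    )
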