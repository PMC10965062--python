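"""Trajectory preprocessing: left/right limb label correction, gap filling,
and zero-lag low-pass filtering.

Pose estimators intermittently exchange left and right limb labels when the
legs cross; short detection dropouts leave gaps in the trajectories; and
pixel noise calls for low-pass smoothing before event detection and angle
computation. The defaults below follow common practice for video-based gait
analysis: linear interpolation of gaps up to 0.12 s, and a zero-lag 4th-order
Butterworth filter (5 Hz for sagittal keypoints, 7 Hz for marker data,
0.4 Hz for the frontal torso size-ratio series).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from . import body25
from .core import TrialKeypoints, Trajectory


@dataclass
class PreprocessConfig:
    """Stream cutoffs and thresholds, overridable per analysis."""

    cutoff_mocap_hz: float = 7.0
    cutoff_sagittal_hz: float = 5.0
    cutoff_sizeratio_hz: float = 0.4
    max_gap_s: float = 0.12
    missing_conf_threshold: float = 0.1


@dataclass
class SwapReport:
    """Frames at which left/right limb labels were exchanged."""

    swapped_frames: list[int] = field(default_factory=list)

    @property
    def n_corrected(self) -> int:
        return len(self.swapped_frames)


def correct_left_right(
    track: TrialKeypoints,
    *,
    pairs: tuple[tuple[int, int], ...] = body25.LOWER_LIMB_PAIRS,
    override_frames: list[int] | None = None,
    margin: float = 0.8,
) -> tuple[TrialKeypoints, SwapReport]:
    """Correct left/right limb label exchanges frame by frame.

    For each frame, the labeling (original or L/R-exchanged over the paired
    limb keypoints) that minimizes the summed displacement from the last
    corrected positions is kept. A swap is applied only when it beats
    keeping the labels by the hysteresis ``margin`` (swap_cost <
    margin × keep_cost): when the legs cross, the two labelings are nearly
    equidistant and without the margin the corrector would flip-flop.
    Correction starts at the first frame where both ankles are present; all
    exchanges are reported. ``override_frames`` forces a swap on the listed
    frames regardless of the displacement test (reproducing a manual
    inspection pass).
    """
    out = track.copy()
    report = SwapReport()
    override = set(override_frames or [])

    l_ankle, r_ankle = body25.L_ANKLE, body25.R_ANKLE
    pair_idx = np.array(pairs)  # (n_pairs, 2) columns: left, right
    left_idx, right_idx = pair_idx[:, 0], pair_idx[:, 1]

    # last corrected position of each paired keypoint
    last = np.full((body25.N_KEYPOINTS, 2), np.nan)
    started = False
    for i in range(out.n_frames):
        frame = out.xy[i]
        if not started:
            if np.isfinite(frame[l_ankle]).all() and np.isfinite(frame[r_ankle]).all():
                started = True
                last[:] = frame
            continue

        if i in override:
            swap = True
        else:
            keep_cost = swap_cost = 0.0
            n_terms = 0
            for li, ri in pairs:
                for cur, prev_keep, prev_swap in (
                    (frame[li], last[li], last[ri]),
                    (frame[ri], last[ri], last[li]),
                ):
                    if np.isfinite(cur).all() and np.isfinite(prev_keep).all() \
                            and np.isfinite(prev_swap).all():
                        keep_cost += float(np.hypot(*(cur - prev_keep)))
                        swap_cost += float(np.hypot(*(cur - prev_swap)))
                        n_terms += 1
            swap = n_terms > 0 and swap_cost < margin * keep_cost

        if swap:
            out.xy[i, left_idx], out.xy[i, right_idx] = (
                frame[right_idx].copy(),
                frame[left_idx].copy(),
            )
            out.confidence[i, left_idx], out.confidence[i, right_idx] = (
                out.confidence[i, right_idx].copy(),
                out.confidence[i, left_idx].copy(),
            )
            report.swapped_frames.append(i)

        observed = np.isfinite(out.xy[i]).all(axis=1)
        last[observed] = out.xy[i][observed]

    # The pass anchors on the first usable frame. If that frame itself was
    # mislabeled, the corrector "fixes" nearly every other frame instead;
    # the majority labeling is then the consistent one, so invert the
    # decision set (the anchor frame was the error).
    processed = [i for i in range(out.n_frames)
                 if np.isfinite(track.xy[i, l_ankle]).all()
                 and np.isfinite(track.xy[i, r_ankle]).all()]
    if processed and len(report.swapped_frames) > 0.5 * len(processed):
        complement = sorted(set(processed) - set(report.swapped_frames))
        out = track.copy()
        for i in complement:
            out.xy[i, left_idx], out.xy[i, right_idx] = (
                track.xy[i, right_idx].copy(),
                track.xy[i, left_idx].copy(),
            )
            out.confidence[i, left_idx], out.confidence[i, right_idx] = (
                track.confidence[i, right_idx].copy(),
                track.confidence[i, left_idx].copy(),
            )
        report.swapped_frames = complement
    return out, report


def fill_gaps(traj: Trajectory, max_gap_s: float = 0.12) -> Trajectory:
    """Linearly interpolate interior missing runs of duration ≤ ``max_gap_s``.

    Gap duration is ``run_length / fps``; the boundary is inclusive. Longer
    runs and leading/trailing runs remain missing. Observed samples are never
    altered, so the operation is idempotent.
    """
    out = traj.copy()
    missing = out.missing
    if not missing.any():
        return out
    n = len(out)
    max_run = int(np.floor(max_gap_s * out.fps + 1e-9))
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        run = j - i
        interior = i > 0 and j < n
        if interior and run <= max_run:
            lo, hi = i - 1, j
            frac = (np.arange(i, j) - lo) / (hi - lo)
            a, b = out.values[lo], out.values[hi]
            if out.values.ndim == 1:
                out.values[i:j] = a + frac * (b - a)
            else:
                out.values[i:j] = a[None, :] + frac[:, None] * (b - a)[None, :]
            out.missing[i:j] = False
        i = j
    return out


def fill_gaps_track(track: TrialKeypoints, max_gap_s: float = 0.12) -> TrialKeypoints:
    """Apply :func:`fill_gaps` to every keypoint trajectory of a trial."""
    out = track.copy()
    for k in range(body25.N_KEYPOINTS):
        filled = fill_gaps(Trajectory(out.xy[:, k, :], out.fps), max_gap_s)
        out.xy[:, k, :] = filled.values
    return out


def lowpass_zero_lag(traj: Trajectory, cutoff_hz: float, order: int = 4) -> Trajectory:
    """Zero-lag low-pass Butterworth filter (forward-backward passes).

    The two passes double the effective order and cancel the phase shift.
    Missing samples inside the filtered span are not allowed — gap-fill or
    trim first. Leading/trailing missing runs are preserved and the observed
    span between them is filtered.
    """
    nyquist = traj.fps / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({nyquist} Hz)")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    out = traj.copy()
    missing = out.missing
    if missing.all():
        return out
    lo = int(np.argmax(~missing))
    hi = len(out) - int(np.argmax(~missing[::-1]))
    if missing[lo:hi].any():
        raise ValueError("interior missing samples: fill gaps before filtering")
    b, a = butter(order, cutoff_hz / nyquist, btype="low")
    span = hi - lo
    padlen = min(span - 1, 3 * max(len(a), len(b)))
    if span > order * 3:
        out.values[lo:hi] = filtfilt(b, a, out.values[lo:hi], axis=0, padlen=padlen)
    return out


def lowpass_track(
    track: TrialKeypoints, cutoff_hz: float, order: int = 4
) -> TrialKeypoints:
    """Filter every keypoint trajectory of a trial (after gap filling)."""
    out = track.copy()
    for k in range(body25.N_KEYPOINTS):
        filt = lowpass_zero_lag(Trajectory(out.xy[:, k, :], out.fps), cutoff_hz, order)
        out.xy[:, k, :] = filt.values
    return out
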