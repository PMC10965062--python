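"""Reading and writing OpenPose BODY_25 JSON, participant tracking, and
conversion to the analysis coordinate conventions.

The OpenPose demo writes one JSON file per video frame of the form::

    {"version": 1.3, "people": [{"pose_keypoints_2d": [x0, y0, c0, ..., x24, y24, c24]}]}

Files sort lexicographically in frame order. Coordinates are 0-based image
pixels with the origin at the top-left corner and y increasing downward.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import body25
from .core import (
    MISSING_CONF_THRESHOLD,
    CameraSetup,
    FrameDetections,
    TrialKeypoints,
)


class OpenPoseFormatError(ValueError):
    """Raised when a JSON file does not follow the OpenPose dialect."""


def read_openpose_frames(directory: str | Path, fps: float) -> list[FrameDetections]:
    """Read a directory of per-frame OpenPose JSON files.

    Files are taken in lexicographic order, which is frame order for the
    OpenPose demo's zero-padded file names. Returns one
    :class:`FrameDetections` per file; a frame with an empty ``people`` list
    yields zero persons.
    """
    directory = Path(directory)
    if fps <= 0:
        raise ValueError("fps must be positive")
    paths = sorted(directory.glob("*.json"))
    # A manifest written alongside synthetic fixtures is not a frame file.
    paths = [p for p in paths if p.name != "manifest.json"]
    frames: list[FrameDetections] = []
    for i, path in enumerate(paths):
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise OpenPoseFormatError(f"malformed JSON in {path.name}: {exc}") from exc
        people = doc.get("people", [])
        persons = np.empty((len(people), body25.N_KEYPOINTS, 3), dtype=float)
        for j, person in enumerate(people):
            flat = np.asarray(person.get("pose_keypoints_2d", []), dtype=float)
            if flat.size != body25.N_KEYPOINTS * 3:
                raise OpenPoseFormatError(
                    f"{path.name}: person {j} has {flat.size} values, "
                    f"expected {body25.N_KEYPOINTS * 3}"
                )
            persons[j] = flat.reshape(body25.N_KEYPOINTS, 3)
        frames.append(FrameDetections(frame_index=i, persons=persons))
    return frames


def write_openpose_json(
    track: TrialKeypoints | np.ndarray,
    directory: str | Path,
    *,
    prefix: str = "frame",
) -> list[Path]:
    """Write a tracked trial (or raw (n, 25, 3) array) as per-frame OpenPose
    JSON files that round-trip exactly through :func:`read_openpose_frames`.

    Missing keypoints are written as (0, 0, 0), OpenPose's absent marker.
    An empty trial writes no frame files but still writes ``manifest.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(track, TrialKeypoints):
        n = track.n_frames
        data = np.concatenate([track.xy, track.confidence[:, :, None]], axis=2)
    else:
        data = np.asarray(track, dtype=float)
        n = data.shape[0]
    data = np.where(np.isfinite(data), data, 0.0)
    width = max(12, len(str(max(n - 1, 0))))
    paths: list[Path] = []
    for i in range(n):
        doc = {
            "version": 1.3,
            "people": [{"pose_keypoints_2d": data[i].ravel().tolist()}],
        }
        path = directory / f"{prefix}_{i:0{width}d}_keypoints.json"
        with open(path, "w") as fh:
            json.dump(doc, fh)
        paths.append(path)
    with open(directory / "manifest.json", "w") as fh:
        json.dump({"n_frames": n, "format": "openpose_body25"}, fh)
    return paths


@dataclass
class TrackReport:
    """Diagnostics from participant tracking across frames."""

    missing_frames: list[int] = field(default_factory=list)
    ambiguous_frames: list[int] = field(default_factory=list)
    chosen_person: list[int] = field(default_factory=list)  # -1 = none


def _anchor_position(person: np.ndarray) -> np.ndarray | None:
    """Tracking anchor: mid-hip if detected, else the confidence-weighted
    centroid of high-confidence keypoints."""
    x, y, c = person[:, 0], person[:, 1], person[:, 2]
    if c[body25.MID_HIP] >= MISSING_CONF_THRESHOLD:
        return person[body25.MID_HIP, :2]
    good = c >= MISSING_CONF_THRESHOLD
    if not good.any():
        return None
    w = c[good]
    return np.array([np.average(x[good], weights=w), np.average(y[good], weights=w)])


def select_person(
    frames: Sequence[FrameDetections],
    seed_frame: int,
    seed_point: tuple[float, float],
    fps: float,
    *,
    jump_threshold_px: float | None = None,
    overrides: dict[int, int] | None = None,
) -> tuple[TrialKeypoints, TrackReport]:
    """Select the participant nearest ``seed_point`` at ``seed_frame`` and
    track them through the trial.

    Tracking proceeds frame-by-frame forward and backward from the seed by
    nearest anchor distance to the last accepted position. A frame whose
    nearest candidate lies beyond ``jump_threshold_px`` (default: 25% of the
    image diagonal, estimated from the observed coordinate range) becomes an
    all-missing frame. Two candidates tied in distance (within 1 px) are
    resolved by higher mean confidence and the frame is logged as ambiguous.
    ``overrides`` pins ``{frame_index: person_index}`` on specific frames.
    """
    if not 0 <= seed_frame < len(frames):
        raise ValueError(f"seed_frame {seed_frame} outside trial of {len(frames)} frames")
    if frames[seed_frame].n_persons == 0:
        raise ValueError(f"no person detected at seed frame {seed_frame}")
    overrides = overrides or {}

    if jump_threshold_px is None:
        coords = [f.persons[:, :, :2][f.persons[:, :, 2] >= MISSING_CONF_THRESHOLD]
                  for f in frames if f.n_persons]
        allc = np.concatenate([c for c in coords if c.size]) if coords else np.zeros((0, 2))
        if allc.size:
            span = allc.max(axis=0) - allc.min(axis=0)
            jump_threshold_px = 0.25 * float(np.hypot(*span))
        else:
            jump_threshold_px = np.inf
        jump_threshold_px = max(jump_threshold_px, 1.0)

    n = len(frames)
    xy = np.full((n, body25.N_KEYPOINTS, 2), np.nan)
    conf = np.zeros((n, body25.N_KEYPOINTS))
    report = TrackReport(chosen_person=[-1] * n)

    def accept(i: int, j: int) -> np.ndarray | None:
        person = frames[i].persons[j]
        detected = person[:, 2] >= MISSING_CONF_THRESHOLD
        xy[i][detected] = person[detected, :2]
        conf[i] = person[:, 2]
        report.chosen_person[i] = j
        return _anchor_position(person)

    def nearest(i: int, ref: np.ndarray) -> tuple[int, float] | None:
        dets = frames[i]
        best: tuple[int, float] | None = None
        dists = []
        for j in range(dets.n_persons):
            anchor = _anchor_position(dets.persons[j])
            if anchor is None:
                continue
            dists.append((j, float(np.hypot(*(anchor - ref)))))
        if not dists:
            return None
        dists.sort(key=lambda jd: jd[1])
        best = dists[0]
        if len(dists) > 1 and dists[1][1] - best[1] < 1.0:
            # near-tie: prefer higher mean confidence, log the frame
            report.ambiguous_frames.append(i)
            tied = [jd for jd in dists if jd[1] - best[1] < 1.0]
            tied.sort(key=lambda jd: -frames[i].persons[jd[0]][:, 2].mean())
            best = tied[0]
        return best

    # seed
    seed = np.asarray(seed_point, dtype=float)
    choice = nearest(seed_frame, seed)
    assert choice is not None
    last = accept(seed_frame, choice[0])

    for direction in (1, -1):
        ref = last
        rng = range(seed_frame + direction, n if direction > 0 else -1, direction)
        for i in rng:
            if i in overrides:
                j = overrides[i]
                if j >= frames[i].n_persons:
                    raise ValueError(f"override frame {i}: person {j} not detected")
                anchor = accept(i, j)
                if anchor is not None:
                    ref = anchor
                continue
            choice = nearest(i, ref) if ref is not None else None
            if choice is None or choice[1] > jump_threshold_px:
                report.missing_frames.append(i)
                continue
            anchor = accept(i, choice[0])
            if anchor is not None:
                ref = anchor

    report.missing_frames.sort()
    track = TrialKeypoints(xy=xy, confidence=conf, fps=fps, view="raw")
    return track, report


def read_override_file(path: str | Path) -> dict[int, int]:
    """Read a CSV of ``frame_index,person_index`` pairs pinning identities."""
    overrides: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.lower().startswith("frame"):
                continue
            a, b = line.split(",")[:2]
            overrides[int(a)] = int(b)
    return overrides


def to_gait_coordinates(
    track: TrialKeypoints,
    setup: CameraSetup,
    *,
    image_height: float | None = None,
) -> TrialKeypoints:
    """Convert raw image coordinates to the analysis conventions.

    Vertical is flipped so positive is up (``y' = H - 1 - y`` with 0-based
    pixels). Horizontal orientation: frontal — positive toward the
    participant's left side (seen from behind while walking away, the
    participant's left is image-left, so x is negated; seen head-on walking
    toward, it is image-right and x is kept); sagittal — positive in the
    direction of travel (left-facing subjects travel toward image-left, so x
    is negated). The transform is affine and invertible and leaves
    confidences untouched.
    """
    if track.view != "raw":
        raise ValueError(f"track already in {track.view!r} coordinates")
    if image_height is None:
        if setup.image_size is not None:
            image_height = setup.image_size[1]
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                image_height = float(np.nanmax(track.xy[:, :, 1])) + 1.0
    out = track.copy()
    out.xy[:, :, 1] = (image_height - 1.0) - out.xy[:, :, 1]
    if _flip_x(setup):
        out.xy[:, :, 0] = -out.xy[:, :, 0]
    out.view = setup.view
    return out


def _flip_x(setup: CameraSetup) -> bool:
    return (setup.view == "frontal" and setup.direction == "away") or (
        setup.view == "sagittal" and setup.direction == "left-facing"
    )


def from_gait_coordinates(
    track: TrialKeypoints, setup: CameraSetup, *, image_height: float
) -> TrialKeypoints:
    """Inverse of :func:`to_gait_coordinates` (the transform is an involution
    on each axis)."""
    out = track.copy()
    if _flip_x(setup):
        out.xy[:, :, 0] = -out.xy[:, :, 0]
    out.xy[:, :, 1] = (image_height - 1.0) - out.xy[:, :, 1]
    out.view = "raw"
    return out
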