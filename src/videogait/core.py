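"""Core data containers shared across the analysis pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from . import body25

View = Literal["frontal", "sagittal"]
#: Frontal walking directions (relative to the camera) and sagittal facings.
Direction = Literal["away", "toward", "left-facing", "right-facing"]

#: Keypoints with confidence below this value are treated as not detected.
MISSING_CONF_THRESHOLD = 0.1


@dataclass
class FrameDetections:
    """All people detected by the pose estimator in one video frame.

    ``persons`` is a float array of shape ``(n_persons, 25, 3)`` holding
    (x, y, confidence) triplets in BODY_25 order, raw image coordinates.
    """

    frame_index: int
    persons: np.ndarray

    def __post_init__(self) -> None:
        self.persons = np.asarray(self.persons, dtype=float)
        if self.persons.size == 0:
            self.persons = self.persons.reshape(0, body25.N_KEYPOINTS, 3)
        if self.persons.ndim != 3 or self.persons.shape[1:] != (body25.N_KEYPOINTS, 3):
            raise ValueError(
                f"frame {self.frame_index}: person array must be "
                f"(n, {body25.N_KEYPOINTS}, 3), got {self.persons.shape}"
            )

    @property
    def n_persons(self) -> int:
        return self.persons.shape[0]


@dataclass
class TrialKeypoints:
    """Keypoint trajectories of the single tracked participant.

    ``xy`` has shape ``(n_frames, 25, 2)``; missing keypoints are NaN.
    ``confidence`` has shape ``(n_frames, 25)``. Frames are consecutive and
    equally spaced; time of frame ``i`` is ``i / fps`` seconds.
    ``view`` is "raw" until :func:`videogait.io.to_gait_coordinates` has
    established the analysis coordinate conventions.
    """

    xy: np.ndarray
    confidence: np.ndarray
    fps: float
    view: str = "raw"

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.xy.ndim != 3 or self.xy.shape[1:] != (body25.N_KEYPOINTS, 2):
            raise ValueError(f"xy must be (n_frames, 25, 2), got {self.xy.shape}")
        if self.confidence.shape != self.xy.shape[:2]:
            raise ValueError("confidence shape must match xy frames/keypoints")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def t(self) -> np.ndarray:
        """Time axis in seconds, frame 0 at t = 0."""
        return np.arange(self.n_frames) / self.fps

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask (n_frames, 25), True where a keypoint is absent."""
        return ~np.isfinite(self.xy).all(axis=2)

    def copy(self) -> "TrialKeypoints":
        return replace(self, xy=self.xy.copy(), confidence=self.confidence.copy())

    def x(self, keypoint: int) -> np.ndarray:
        return self.xy[:, keypoint, 0]

    def y(self, keypoint: int) -> np.ndarray:
        return self.xy[:, keypoint, 1]


@dataclass
class CameraSetup:
    """Camera and recording metadata needed to run an analysis.

    Frontal view requires ``d_ref_m``, the depth (m) of the participant from
    the camera at the start of the trial. Sagittal view requires a known
    physical distance along the line of progression and its length in pixels,
    used to convert pixel excursions to meters.
    """

    view: View
    direction: Direction
    fps: float
    d_ref_m: float | None = None
    calibration_distance_m: float | None = None
    calibration_distance_px: float | None = None
    image_size: tuple[int, int] | None = None  # (width, height) px

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.view == "frontal":
            if self.direction not in ("away", "toward"):
                raise ValueError(f"frontal direction must be away/toward, got {self.direction!r}")
            if self.d_ref_m is None or self.d_ref_m <= 0:
                raise ValueError("frontal view requires d_ref_m > 0")
        elif self.view == "sagittal":
            if self.direction not in ("left-facing", "right-facing"):
                raise ValueError(
                    f"sagittal direction must be left-facing/right-facing, got {self.direction!r}"
                )
            if not self.calibration_distance_m or self.calibration_distance_m <= 0:
                raise ValueError("sagittal view requires calibration_distance_m > 0")
            if not self.calibration_distance_px or self.calibration_distance_px <= 0:
                raise ValueError("sagittal view requires calibration_distance_px > 0")
        else:
            raise ValueError(f"unknown view {self.view!r}")


@dataclass
class Trajectory:
    """A scalar or 2-vector time series with an explicit missing mask."""

    values: np.ndarray
    fps: float
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
            if self.values.ndim > 1:
                self.missing = self.missing.any(axis=-1)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape[0] != self.values.shape[0]:
            raise ValueError("missing mask length must match values")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) / self.fps

    def copy(self) -> "Trajectory":
        return Trajectory(self.values.copy(), self.fps, self.missing.copy())
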