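"""Core data containers: pose tracks, frame stacks, labeled clips.

Coordinate convention used throughout the package: a right-handed
mathematical frame with x increasing rightward and y increasing upward,
in millimetres. Raster (image) coordinates are y-down; they are flipped
once at load (see :func:`swimpose.io.read_pose_table`) so that every
geometric operation downstream can assume y-up and "head up" = +y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .skeleton import N_KEYPOINTS

#: Frame rate of the multi-well acquisition, frames per second.
DEFAULT_FPS = 160.0

#: Spatial calibration: a 6.38 mm diameter well spanning 256 px.
DEFAULT_MM_PER_PX = 0.0249

#: Well radius in mm from the 0.32 cm^2 circular well area.
DEFAULT_WELL_RADIUS_MM = 3.19

EPOCH_LABELS = ("baseline", "TP1", "TP2", "other")

#: The five behavior classes, ordered from least to most severe.
BEHAVIOR_CLASSES = (
    "stationary",
    "normal_swim",
    "whirlpool",
    "convulsion",
    "posture_loss",
)


@dataclass
class PoseTrack:
    """Time series of 8 key-point coordinates for one larva in one well.

    Attributes
    ----------
    coords
        ``(T, 8, 2)`` float array. Invalid frames may hold NaN.
    valid
        ``(T,)`` boolean mask; False marks frames removed by cleaning or
        missing from the source table.
    unit
        ``"mm"`` (canonical) or ``"px"``.
    """

    coords: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    fps: float = DEFAULT_FPS
    mm_per_px: float = DEFAULT_MM_PER_PX
    unit: str = "mm"
    well_id: str = ""
    epoch_label: str = "other"
    well_center: np.ndarray = None  # type: ignore[assignment]
    well_radius: float = DEFAULT_WELL_RADIUS_MM

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_KEYPOINTS, 2):
            raise ValueError(f"coords must have shape (T, {N_KEYPOINTS}, 2), got {self.coords.shape}")
        if self.valid is None:
            self.valid = np.all(np.isfinite(self.coords), axis=(1, 2))
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (self.coords.shape[0],):
            raise ValueError("valid mask length must equal number of frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.well_radius <= 0:
            raise ValueError("well_radius must be positive")
        if self.unit not in ("mm", "px"):
            raise ValueError(f"unit must be 'mm' or 'px', got {self.unit!r}")
        if self.epoch_label not in EPOCH_LABELS:
            raise ValueError(f"epoch_label must be one of {EPOCH_LABELS}")
        if self.well_center is None:
            self.well_center = np.zeros(2)
        self.well_center = np.asarray(self.well_center, dtype=float)
        if not np.all(np.isfinite(self.coords[self.valid])):
            raise ValueError("coordinates must be finite on valid frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def to_mm(self) -> "PoseTrack":
        """Return a copy in mm; exact multiplicative conversion from px."""
        if self.unit == "mm":
            return self.copy()
        s = self.mm_per_px
        return replace(
            self,
            coords=self.coords * s,
            valid=self.valid.copy(),
            well_center=self.well_center * s,
            well_radius=self.well_radius * s,
            unit="mm",
        )

    def to_px(self) -> "PoseTrack":
        if self.unit == "px":
            return self.copy()
        s = self.mm_per_px
        return replace(
            self,
            coords=self.coords / s,
            valid=self.valid.copy(),
            well_center=self.well_center / s,
            well_radius=self.well_radius / s,
            unit="px",
        )

    def copy(self) -> "PoseTrack":
        return replace(self, coords=self.coords.copy(), valid=self.valid.copy(), well_center=self.well_center.copy())


@dataclass
class FrameStack:
    """Ordered grayscale frames for one well.

    All frames share one ``(m, n)`` shape and hold non-negative integer
    pixel values — the substrate of the pixel-change activity metric.
    """

    frames: np.ndarray
    well_id: str = ""
    fps: float = DEFAULT_FPS
    epoch_label: str = "other"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be a (T, m, n) grayscale stack, got ndim={self.frames.ndim}; "
                             "convert RGB input to grayscale first")
        if np.issubdtype(self.frames.dtype, np.signedinteger) and self.frames.min() < 0:
            raise ValueError("pixel values must be non-negative")
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise ValueError("frames must hold integer pixel values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class LabeledClip:
    """One 60-frame pose segment with a behavior-class label."""

    clip_id: str
    coords: np.ndarray  # (window_len, 8, 2), mm, y-up
    label: str
    track_id: str = ""
    start_frame: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_KEYPOINTS, 2):
            raise ValueError("clip coords must have shape (L, 8, 2)")
        if self.label not in BEHAVIOR_CLASSES:
            raise ValueError(f"label {self.label!r} not in {BEHAVIOR_CLASSES}")


@dataclass
class LabeledClipSet:
    """A set of labeled clips; duplicate (track, start-frame) pairs rejected."""

    clips: list[LabeledClip] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for c in self.clips:
            key = (c.track_id, c.start_frame)
            if c.track_id and key in seen:
                raise ValueError(f"duplicate clip identity {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.clips)

    def __iter__(self):
        return iter(self.clips)

    def labels(self) -> list[str]:
        return [c.label for c in self.clips]

    def by_class(self) -> dict[str, list[LabeledClip]]:
        out: dict[str, list[LabeledClip]] = {c: [] for c in BEHAVIOR_CLASSES}
        for clip in self.clips:
            out[clip.label].append(clip)
        return {k: v for k, v in out.items() if v}

    def subset(self, clips: Sequence[LabeledClip]) -> "LabeledClipSet":
        return LabeledClipSet(list(clips))
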