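"""Sliding windows and egocentric alignment of pose segments.

Tracks are segmented into overlapping 60-frame windows (0.375 s at
160 fps). A single rigid transform — computed from the first frame of
each window — rotates the fish so its heading (center -> snout) points
along canonical "up" (+y) and translates the center key-point to the
origin; the same transform is applied unchanged to the remaining 59
frames, so within-window motion is preserved while absolute position and
orientation in the well are removed. The aligned (60, 8, 2) block
flattens in frame-major, key-point-major, (x, y) order to a 960-length
feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import SkeletonSpec, DEFAULT_SKELETON, N_KEYPOINTS
from .track import PoseTrack

#: Canonical heading after alignment ("head up").
CANONICAL_UP = np.array([0.0, 1.0])


@dataclass(frozen=True)
class WindowingParams:
    """window_len frames per window (default 60), start positions every
    ``stride`` frames; incomplete or invalid-containing windows dropped."""

    window_len: int = 60
    stride: int = 15
    drop_incomplete: bool = True

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")
        if not (1 <= self.stride <= self.window_len):
            raise ValueError("stride must satisfy 1 <= stride <= window_len")


@dataclass
class RawWindow:
    """Un-aligned pose window cut from a track."""

    coords: np.ndarray  # (window_len, 8, 2)
    start_frame: int
    track_id: str = ""


def make_windows(track: PoseTrack, params: WindowingParams = WindowingParams()) -> list[RawWindow]:
    """Cut overlapping windows starting at frames 0, stride, 2*stride, ...

    Windows containing any invalid (cleaned-out) frame are dropped when
    ``drop_incomplete`` — masked frames are never interpolated. A track
    shorter than one window yields an empty list.
    """
    L = params.window_len
    out = []
    for start in range(0, track.n_frames - L + 1, params.stride):
        if params.drop_incomplete and not track.valid[start:start + L].all():
            continue
        out.append(RawWindow(coords=track.coords[start:start + L].copy(),
                             start_frame=start, track_id=track.well_id))
    return out


def alignment_transform(first_frame: np.ndarray, skeleton: SkeletonSpec = DEFAULT_SKELETON) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix and pivot aligning one frame's heading to +y.

    Returns (R, pivot) such that ``(coords - pivot) @ R.T`` maps the
    frame's center key-point to the origin and its heading to
    :data:`CANONICAL_UP`. Raises on a degenerate (zero-length) heading.
    """
    pivot = first_frame[skeleton.center]
    h = first_frame[skeleton.snout] - pivot
    n = np.linalg.norm(h)
    if n == 0 or not np.isfinite(n):
        raise ValueError("degenerate heading in the window's first frame")
    u = h / n
    # rotate u onto (0, 1): R = [[uy, -ux], [ux, uy]]
    R = np.array([[u[1], -u[0]], [u[0], u[1]]])
    return R, pivot


def egocentric_align(window: np.ndarray, skeleton: SkeletonSpec = DEFAULT_SKELETON) -> np.ndarray:
    """Apply the first frame's rigid transform identically to all frames.

    The output's first frame has its center key-point at the origin and
    heading exactly along +y; later frames are transformed by the same
    matrix, not re-canonicalized, so pairwise key-point distances and
    within-window motion are untouched.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 3 or window.shape[1:] != (N_KEYPOINTS, 2):
        raise ValueError(f"window must have shape (L, {N_KEYPOINTS}, 2)")
    R, pivot = alignment_transform(window[0], skeleton)
    return (window - pivot) @ R.T


def flatten_features(aligned: np.ndarray) -> np.ndarray:
    """Flatten an aligned (L, 8, 2) window to a length-16L vector
    (frame-major, then key-point, then x before y); 60 frames -> 960."""
    aligned = np.asarray(aligned, dtype=float)
    if aligned.ndim != 3 or aligned.shape[1:] != (N_KEYPOINTS, 2):
        raise ValueError("expected an (L, 8, 2) window")
    return aligned.reshape(-1)


def unflatten_features(vec: np.ndarray, window_len: int = 60) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.size != window_len * N_KEYPOINTS * 2:
        raise ValueError(f"expected a vector of length {window_len * N_KEYPOINTS * 2}")
    return vec.reshape(window_len, N_KEYPOINTS, 2)
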