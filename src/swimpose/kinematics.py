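"""Per-frame swim kinematics: speed, distance, tail angle, heading change,
inter-eye distance.

Conventions (all in the package's y-up mm frame):

* heading vector = center -> snout, pointing where the animal faces;
* body-axis vector = snout -> center; the tail angle theta is the
  unsigned angle between the tail vector (center -> caudal fin) and the
  caudal extension of the body axis, so a straight, fully extended larva
  reads 0 deg and a larva curled until the tail tip touches the snout
  reads 180 deg;
* heading change is the signed frame-to-frame rotation of the heading
  vector, counterclockwise-positive, wrapped to (-180, 180];
* inter-eye distance is the Euclidean distance between the eye
  key-points — approximately 0.2 mm for an upright larva, collapsing
  toward 0 when the larva lies on its side (posture loss).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .skeleton import SkeletonSpec, DEFAULT_SKELETON
from .cleaning import track_com, _gap_speeds
from .track import PoseTrack


@dataclass
class KinematicSeries:
    """Frame-aligned kinematic scalars plus epoch summaries for one track."""

    frame: np.ndarray
    com: np.ndarray              # (T, 2) mm, NaN where invalid
    speed: np.ndarray            # mm/s, NaN on first valid frame / invalid
    dist_cum: np.ndarray         # cumulative distance, metres
    tail_angle: np.ndarray       # deg in [0, 180]
    heading_change: np.ndarray   # deg in (-180, 180], signed
    inter_eye: np.ndarray        # mm
    fps: float
    well_id: str = ""
    epoch_label: str = "other"

    @property
    def max_speed(self) -> float:
        s = self.speed[np.isfinite(self.speed)]
        return float(s.max()) if s.size else float("nan")

    @property
    def total_distance_m(self) -> float:
        d = self.dist_cum[np.isfinite(self.dist_cum)]
        return float(d[-1]) if d.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.frame,
            "com_x": self.com[:, 0], "com_y": self.com[:, 1],
            "speed": self.speed, "dist_cum": self.dist_cum,
            "tail_angle": self.tail_angle,
            "heading_change": self.heading_change,
            "inter_eye": self.inter_eye,
        })


def _wrap_angle(deg: np.ndarray) -> np.ndarray:
    """Wrap to (-180, 180], keeping +180 at the boundary."""
    wrapped = (np.asarray(deg) + 180.0) % 360.0 - 180.0
    return np.where(np.isclose(wrapped, -180.0), 180.0, wrapped)


def speed_series(track: PoseTrack, skeleton: SkeletonSpec = DEFAULT_SKELETON) -> tuple[np.ndarray, np.ndarray]:
    """Gap-aware COM speed (mm/s) and cumulative distance (m) per frame.

    Speed at a valid frame is the COM displacement from the previous
    valid frame divided by the elapsed time across the gap; it is NaN on
    the first valid frame of the track. Cumulative distance sums valid
    displacements and is reported in metres.
    """
    if track.valid.sum() < 2:
        raise ValueError("need at least 2 valid frames for speeds")
    com = track_com(track, skeleton)
    speed = _gap_speeds(com, track.valid, track.fps)
    dist = np.full(track.n_frames, np.nan)
    idx = np.flatnonzero(track.valid)
    steps = np.linalg.norm(com[idx[1:]] - com[idx[:-1]], axis=1)
    dist[idx] = np.concatenate([[0.0], np.cumsum(steps)]) / 1000.0
    return speed, dist


def tail_angle(snout: np.ndarray, center: np.ndarray, caudal_fin: np.ndarray) -> np.ndarray:
    """Unsigned tail bend in degrees, 0 (straight) to 180 (fully curled).

    Measured between the tail vector (center -> caudal fin) and the
    caudal extension of the body axis (the snout -> center direction).
    NaN where either vector has zero length (coincident key-points).
    """
    snout, center, caudal_fin = (np.asarray(a, dtype=float) for a in (snout, center, caudal_fin))
    body = center - snout          # caudal extension of the body axis
    tail = caudal_fin - center
    nb = np.linalg.norm(body, axis=-1)
    nt = np.linalg.norm(tail, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.sum(body * tail, axis=-1) / (nb * nt)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return np.where((nb > 0) & (nt > 0), ang, np.nan)


def heading_angles(track: PoseTrack, skeleton: SkeletonSpec = DEFAULT_SKELETON) -> np.ndarray:
    """Absolute heading of the center -> snout vector, degrees CCW from +x."""
    h = track.coords[:, skeleton.snout, :] - track.coords[:, skeleton.center, :]
    ang = np.degrees(np.arctan2(h[:, 1], h[:, 0]))
    zero = np.linalg.norm(h, axis=1) == 0
    ang[zero | ~track.valid] = np.nan
    return ang


def heading_change(track: PoseTrack, skeleton: SkeletonSpec = DEFAULT_SKELETON) -> np.ndarray:
    """Signed heading rotation vs the previous valid frame, (-180, 180].

    Counterclockwise-positive in the y-up frame; NaN on the first valid
    frame and wherever the heading vector degenerates to zero length.
    """
    ang = heading_angles(track, skeleton)
    out = np.full(track.n_frames, np.nan)
    idx = np.flatnonzero(np.isfinite(ang))
    if len(idx) >= 2:
        out[idx[1:]] = _wrap_angle(ang[idx[1:]] - ang[idx[:-1]])
    return out


def inter_eye_distance(track: PoseTrack, skeleton: SkeletonSpec = DEFAULT_SKELETON) -> np.ndarray:
    """Euclidean eye-to-eye distance per frame (mm); NaN on invalid frames."""
    d = np.linalg.norm(track.coords[:, skeleton.eye_left, :] - track.coords[:, skeleton.eye_right, :], axis=1)
    d = d.astype(float)
    d[~track.valid] = np.nan
    return d


def kinematic_series(track: PoseTrack, skeleton: SkeletonSpec = DEFAULT_SKELETON) -> KinematicSeries:
    """All per-frame metrics, time-aligned on the same frame index."""
    if track.unit != "mm":
        track = track.to_mm()
    speed, dist = speed_series(track, skeleton)
    s = track.coords[:, skeleton.snout, :]
    c = track.coords[:, skeleton.center, :]
    f = track.coords[:, skeleton.caudal_fin, :]
    theta = tail_angle(s, c, f)
    theta[~track.valid] = np.nan
    return KinematicSeries(
        frame=np.arange(track.n_frames),
        com=track_com(track, skeleton),
        speed=speed,
        dist_cum=dist,
        tail_angle=theta,
        heading_change=heading_change(track, skeleton),
        inter_eye=inter_eye_distance(track, skeleton),
        fps=track.fps,
        well_id=track.well_id,
        epoch_label=track.epoch_label,
    )
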