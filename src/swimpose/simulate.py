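"""Synthetic larval pose-track generator for the five behavior classes.

Every pipeline stage is testable without recorded video: the generator
produces 8-key-point tracks with programmed, recoverable kinematics and
per-frame ground-truth labels.

Body model: six midline key-points along a 4 mm polyline (snout,
rostral trunk, center, caudal trunk, mid tail, caudal fin) with the tail
bend realized as a progressive rotation of the caudal segments so that
the chord from center to caudal fin makes exactly the programmed tail
angle with the body axis; the eyes sit 0.1 mm either side of the snout
axis (inter-eye distance ~0.2 mm), collapsing to ~0.01 mm apart when the
posture-loss flag is set (larva on its side, one eye visible). Each
frame is recentered so the midline center of mass follows the programmed
trajectory exactly, which makes programmed speeds directly recoverable
from measured COM kinematics.

Class trajectories:

* stationary — no translation, straight tail;
* normal_swim — burst-and-glide: 150 ms speed bursts (peak 30 mm/s)
  alternating with 350 ms glides, gentle heading wander, walls avoided
  by steering back toward the well center;
* whirlpool — orbit along the well perimeter at a programmed tangential
  speed (default 60 mm/s, radius 2.5 mm), heading tangential;
* convulsion — fast sinusoidal whole-body movement: COM oscillates along
  a slowly rotating axis with peak speed ~110 mm/s, large left-right
  tail bends (amplitude 150 deg) and violent heading wobble;
* posture_loss — near-static with collapsed inter-eye distance and a
  constant moderate tail bend.

Isotropic Gaussian positional jitter (default sd 0.02 mm, below typical
pose-estimation error) is added to every key-point; sd 0 gives bitwise
repeatable, perfectly still stationary frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .skeleton import SkeletonSpec, DEFAULT_SKELETON
from .track import (PoseTrack, FrameStack, LabeledClip, LabeledClipSet,
                    BEHAVIOR_CLASSES, DEFAULT_FPS, DEFAULT_MM_PER_PX, DEFAULT_WELL_RADIUS_MM)

#: Total midline length, mm (typical larval body length).
BODY_LENGTH_MM = 4.0
_SEG = BODY_LENGTH_MM / 5.0  # 0.8 mm between adjacent midline points
_EYE_BACK = 0.3              # eyes sit 0.3 mm caudal of the snout
_COLLAPSED_EYE_MM = 0.01


@dataclass(frozen=True)
class SimWell:
    """Geometry and acquisition parameters of one simulated well."""

    radius_mm: float = DEFAULT_WELL_RADIUS_MM   # from the 0.32 cm^2 well area
    fps: float = DEFAULT_FPS
    mm_per_px: float = DEFAULT_MM_PER_PX
    frame_size: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.fps <= 0 or self.mm_per_px <= 0:
            raise ValueError("well radius, fps and mm_per_px must be positive")


@dataclass(frozen=True)
class MotifParams:
    """Programmed kinematics of one behavior motif."""

    behavior: str
    duration_s: float = 2.0
    speed_mm_s: float = 0.0          # burst peak / tangential / oscillation peak
    tail_amplitude_deg: float = 0.0
    tail_freq_hz: float = 0.0
    heading_rate_deg_s: float = 0.0
    inter_eye_mm: float = 0.2
    posture_collapse: bool = False
    noise_sd_mm: float = 0.02
    orbit_radius_mm: float = 2.5     # whirlpool only
    osc_freq_hz: float = 10.0        # convulsion COM oscillation
    burst_s: float = 0.15
    glide_s: float = 0.35
    glide_speed_mm_s: float = 2.0
    tail_offset_deg: float = 0.0     # constant bend (posture loss)

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIOR_CLASSES:
            raise ValueError(f"behavior must be one of {BEHAVIOR_CLASSES}")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.speed_mm_s < 0:
            raise ValueError("speeds must be non-negative")
        if not (0 <= self.tail_amplitude_deg <= 180):
            raise ValueError("tail amplitude must lie in [0, 180] deg")


_CLASS_DEFAULTS: dict[str, dict] = {
    "stationary": dict(speed_mm_s=0.0, tail_amplitude_deg=0.0),
    "normal_swim": dict(speed_mm_s=30.0, tail_amplitude_deg=25.0, tail_freq_hz=20.0),
    "whirlpool": dict(speed_mm_s=60.0, tail_amplitude_deg=40.0, tail_freq_hz=15.0),
    "convulsion": dict(speed_mm_s=110.0, tail_amplitude_deg=150.0, tail_freq_hz=10.0,
                       heading_rate_deg_s=90.0),
    "posture_loss": dict(speed_mm_s=0.0, tail_amplitude_deg=0.0, tail_offset_deg=25.0,
                         posture_collapse=True),
}


def motif_params(behavior: str, duration_s: float = 2.0, **overrides) -> MotifParams:
    """Default motif parameters for a behavior class, with overrides."""
    if behavior not in _CLASS_DEFAULTS:
        raise ValueError(f"unknown behavior {behavior!r}")
    kw = dict(_CLASS_DEFAULTS[behavior])
    kw.update(overrides)
    return MotifParams(behavior=behavior, duration_s=duration_s, **kw)


@dataclass
class GroundTruth:
    """Programmed per-frame kinematics returned next to each track."""

    label: str
    speed: np.ndarray        # mm/s, NaN on frame 0
    tail_angle: np.ndarray   # deg, unsigned
    inter_eye: np.ndarray    # mm
    heading_deg: np.ndarray
    com: np.ndarray          # (T, 2) programmed COM, mm


def _unit(angle_deg: np.ndarray) -> np.ndarray:
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return np.stack([np.cos(a), np.sin(a)], axis=-1)


def _pose_coords(pos: np.ndarray, heading_deg: np.ndarray, tail_signed_deg: np.ndarray,
                 inter_eye: np.ndarray, skeleton: SkeletonSpec) -> np.ndarray:
    """Vectorized body model: (T,) trajectories -> (T, 8, 2) key-points.

    Builds the pose about the snout, then recenters every frame so the
    6-point midline COM equals ``pos`` exactly.
    """
    T = len(heading_deg)
    back = heading_deg + 180.0  # caudal direction
    chord = 2.4 - 0.8 * np.abs(tail_signed_deg) / 180.0  # tail tip meets snout at 180
    snout = np.zeros((T, 2))
    rostral = _SEG * _unit(back)
    center = 2 * _SEG * _unit(back)
    caudal_trunk = center + _SEG * _unit(back + tail_signed_deg / 3.0)
    mid_tail = caudal_trunk + _SEG * _unit(back + 2.0 * tail_signed_deg / 3.0)
    caudal_fin = center + chord[:, None] * _unit(back + tail_signed_deg)
    normal = _unit(heading_deg + 90.0)
    eye_base = snout + _EYE_BACK * _unit(back)
    eye_left = eye_base + (inter_eye / 2.0)[:, None] * normal
    eye_right = eye_base - (inter_eye / 2.0)[:, None] * normal

    coords = np.empty((T, 8, 2))
    role_pts = {"snout": snout, "eye_left": eye_left, "eye_right": eye_right,
                "rostral_trunk": rostral, "center": center,
                "caudal_trunk": caudal_trunk, "mid_tail": mid_tail,
                "caudal_fin": caudal_fin}
    for i, role in enumerate(skeleton.order):
        coords[:, i, :] = role_pts[role]
    com = coords[:, list(skeleton.midline_indices), :].mean(axis=1)
    return coords - com[:, None, :] + np.asarray(pos)[:, None, :]


def _tail_series(p: MotifParams, t: np.ndarray, phase: float) -> np.ndarray:
    tail = np.full(t.shape, p.tail_offset_deg)
    if p.tail_amplitude_deg > 0 and p.tail_freq_hz > 0:
        tail = tail + p.tail_amplitude_deg * np.sin(2 * np.pi * p.tail_freq_hz * t + phase)
    return tail


def _traj_static(p: MotifParams, well: SimWell, T: int, start: np.ndarray,
                 heading0: float, rng: np.random.Generator):
    t = np.arange(T) / well.fps
    pos = np.tile(start, (T, 1))
    heading = np.full(T, heading0)
    tail = _tail_series(p, t, phase=rng.uniform(0, 2 * np.pi))
    return pos, heading, tail


def _traj_burst_glide(p: MotifParams, well: SimWell, T: int, start: np.ndarray,
                      heading0: float, rng: np.random.Generator):
    dt = 1.0 / well.fps
    t = np.arange(T) * dt
    cycle = p.burst_s + p.glide_s
    phase_in_cycle = t % cycle
    in_burst = phase_in_cycle < p.burst_s
    speed = np.where(in_burst,
                     p.speed_mm_s * np.sin(np.pi * phase_in_cycle / p.burst_s) ** 2,
                     p.glide_speed_mm_s)
    pos = np.empty((T, 2))
    heading = np.empty(T)
    pos[0], heading[0] = start, heading0
    turn = rng.normal(0.0, 2.0, size=T) * in_burst  # wander only while bursting
    for i in range(1, T):
        h = heading[i - 1] + turn[i]
        step = speed[i] * dt * _unit(h)
        nxt = pos[i - 1] + step
        if np.linalg.norm(nxt) > 0.8 * well.radius_mm:
            # steer back toward the well center
            h = math.degrees(math.atan2(-pos[i - 1][1], -pos[i - 1][0])) + rng.normal(0, 5.0)
            nxt = pos[i - 1] + speed[i] * dt * _unit(h)
        heading[i], pos[i] = h, nxt
    tail = _tail_series(p, t, phase=rng.uniform(0, 2 * np.pi)) * in_burst
    return pos, heading, tail


def _traj_whirlpool(p: MotifParams, well: SimWell, T: int, start: np.ndarray,
                    heading0: float, rng: np.random.Generator):
    if p.orbit_radius_mm >= well.radius_mm:
        raise ValueError(f"orbit radius {p.orbit_radius_mm} mm does not fit in a "
                         f"{well.radius_mm} mm well")
    dt = 1.0 / well.fps
    t = np.arange(T) * dt
    r0 = float(np.linalg.norm(start))
    ramp_s = min(0.25, T * dt / 4.0)
    radius = np.where(t < ramp_s,
                      r0 + (p.orbit_radius_mm - r0) * t / max(ramp_s, dt),
                      p.orbit_radius_mm)
    # integrate dphi/dt = v / r(t) so tangential speed stays programmed
    omega = p.speed_mm_s / np.maximum(radius, 1e-6)
    phi0 = math.atan2(start[1], start[0]) if r0 > 1e-9 else rng.uniform(0, 2 * np.pi)
    phi = phi0 + np.concatenate([[0.0], np.cumsum(omega[:-1]) * dt])
    pos = radius[:, None] * np.stack([np.cos(phi), np.sin(phi)], axis=1)
    heading = np.degrees(phi) + 90.0  # tangential, counterclockwise orbit
    tail = _tail_series(p, t, phase=rng.uniform(0, 2 * np.pi))
    return pos, heading, tail


def _traj_convulsion(p: MotifParams, well: SimWell, T: int, start: np.ndarray,
                     heading0: float, rng: np.random.Generator):
    dt = 1.0 / well.fps
    t = np.arange(T) * dt
    amp = p.speed_mm_s / (2 * np.pi * p.osc_freq_hz)  # peak COM speed = programmed
    max_base = max(well.radius_mm - amp - 0.3, 0.0)
    start = np.asarray(start, dtype=float)
    nb = np.linalg.norm(start)
    target = start * (max_base / nb) if nb > max_base and nb > 0 else start
    # ease the base point in from the handoff position and grow the
    # oscillation with it, so concatenated epochs have no COM teleports
    ramp = np.minimum(t / 0.5, 1.0) if T > 1 else np.ones(1)
    base = start + ramp[:, None] * (target - start)
    amp_eff = amp * ramp
    psi = heading0 + p.heading_rate_deg_s * t  # slowly rotating thrash axis
    pos = base + (amp_eff * np.sin(2 * np.pi * p.osc_freq_hz * t))[:, None] * _unit(psi)
    wobble = 70.0 * np.sin(2 * np.pi * p.tail_freq_hz * t + rng.uniform(0, 2 * np.pi))
    heading = psi + wobble
    tail = _tail_series(p, t, phase=rng.uniform(0, 2 * np.pi))
    return pos, heading, tail


_TRAJ = {
    "stationary": _traj_static,
    "posture_loss": _traj_static,
    "normal_swim": _traj_burst_glide,
    "whirlpool": _traj_whirlpool,
    "convulsion": _traj_convulsion,
}


def _finish(pos, heading, tail, p: MotifParams, well: SimWell,
            rng: np.random.Generator, skeleton: SkeletonSpec,
            well_id: str) -> tuple[PoseTrack, GroundTruth]:
    T = len(heading)
    inter_eye = np.full(T, _COLLAPSED_EYE_MM if p.posture_collapse else p.inter_eye_mm)
    coords = _pose_coords(pos, heading, tail, inter_eye, skeleton)
    if p.noise_sd_mm > 0:
        coords = coords + rng.normal(0.0, p.noise_sd_mm, size=coords.shape)
    track = PoseTrack(coords=coords, fps=well.fps, mm_per_px=well.mm_per_px,
                      unit="mm", well_id=well_id, well_center=np.zeros(2),
                      well_radius=well.radius_mm)
    speed = np.full(T, np.nan)
    speed[1:] = np.linalg.norm(np.diff(pos, axis=0), axis=1) * well.fps
    gt = GroundTruth(label=p.behavior, speed=speed, tail_angle=np.abs(tail),
                     inter_eye=inter_eye, heading_deg=heading, com=pos)
    return track, gt


def simulate_motif(params: MotifParams, well: SimWell = SimWell(), seed: int = 0,
                   start_pos: np.ndarray | None = None, start_heading: float | None = None,
                   skeleton: SkeletonSpec = DEFAULT_SKELETON,
                   well_id: str = "sim") -> tuple[PoseTrack, str, GroundTruth]:
    """Simulate one behavior motif; reproducible under ``seed``.

    Returns the track, its class label, and the programmed ground-truth
    kinematics (speed, tail angle, inter-eye distance per frame).
    """
    rng = np.random.default_rng(seed)
    T = int(round(params.duration_s * well.fps))
    if T < 1:
        raise ValueError("motif too short for one frame")
    if start_pos is None:
        r = rng.uniform(0, 0.5 * well.radius_mm)
        a = rng.uniform(0, 2 * np.pi)
        start_pos = r * np.array([np.cos(a), np.sin(a)])
    if start_heading is None:
        start_heading = rng.uniform(0, 360)
    pos, heading, tail = _TRAJ[params.behavior](params, well, T,
                                                np.asarray(start_pos, dtype=float),
                                                float(start_heading), rng)
    track, gt = _finish(pos, heading, tail, params, well, rng, skeleton, well_id)
    return track, params.behavior, gt


def simulate_epoch(schedule: list[tuple[str, float]], well: SimWell = SimWell(),
                   seed: int = 0, skeleton: SkeletonSpec = DEFAULT_SKELETON,
                   well_id: str = "sim", noise_sd_mm: float = 0.02,
                   ) -> tuple[PoseTrack, np.ndarray, GroundTruth]:
    """Concatenate motifs into one epoch with a continuous COM trajectory.

    ``schedule`` is a list of (behavior class, duration in seconds)
    totalling at most 300 s. Per-frame true labels are returned alongside
    the track. Deterministic under ``seed``.
    """
    if not schedule:
        raise ValueError("schedule is empty")
    if sum(d for _, d in schedule) > 300.0 + 1e-9:
        raise ValueError("schedule exceeds the 300 s epoch length")
    rng = np.random.default_rng(seed)
    pos_parts, head_parts, tail_parts, ie_parts, labels = [], [], [], [], []
    cur_pos = None
    cur_heading = None
    for behavior, duration in schedule:
        p = motif_params(behavior, duration_s=duration, noise_sd_mm=noise_sd_mm)
        T = int(round(duration * well.fps))
        if cur_pos is None:
            r = rng.uniform(0, 0.5 * well.radius_mm)
            a = rng.uniform(0, 2 * np.pi)
            cur_pos = r * np.array([np.cos(a), np.sin(a)])
            cur_heading = rng.uniform(0, 360)
        pos, heading, tail = _TRAJ[behavior](p, well, T, cur_pos, cur_heading, rng)
        pos_parts.append(pos)
        head_parts.append(heading)
        tail_parts.append(tail)
        ie_parts.append(np.full(T, _COLLAPSED_EYE_MM if p.posture_collapse else p.inter_eye_mm))
        labels.extend([behavior] * T)
        cur_pos, cur_heading = pos[-1], float(heading[-1] % 360.0)
    pos = np.concatenate(pos_parts)
    heading = np.concatenate(head_parts)
    tail = np.concatenate(tail_parts)
    inter_eye = np.concatenate(ie_parts)
    coords = _pose_coords(pos, heading, tail, inter_eye, skeleton)
    if noise_sd_mm > 0:
        coords = coords + rng.normal(0.0, noise_sd_mm, size=coords.shape)
    track = PoseTrack(coords=coords, fps=well.fps, mm_per_px=well.mm_per_px,
                      unit="mm", well_id=well_id, well_center=np.zeros(2),
                      well_radius=well.radius_mm)
    speed = np.full(len(pos), np.nan)
    speed[1:] = np.linalg.norm(np.diff(pos, axis=0), axis=1) * well.fps
    gt = GroundTruth(label="mixed", speed=speed, tail_angle=np.abs(tail),
                     inter_eye=inter_eye, heading_deg=heading, com=pos)
    return track, np.array(labels, dtype=object), gt


def render_frames(track: PoseTrack, well: SimWell = SimWell()) -> FrameStack:
    """Rasterize a track into grayscale frames (bright well, dark larva).

    The larva body is drawn as overlapping disks of tapering radius along
    the interpolated midline; rendering is deterministic, so a noiseless
    stationary track produces bitwise-identical frames.
    """
    from skimage.draw import disk

    ny, nx = well.frame_size
    bg, fg = 220, 30
    track = track.to_mm()
    skeleton = DEFAULT_SKELETON
    mid_idx = list(skeleton.midline_indices)
    frames = np.full((track.n_frames, ny, nx), bg, dtype=np.uint8)
    # radius tapers head -> tail, in px
    taper = np.linspace(0.14, 0.05, 24) / well.mm_per_px
    for i in range(track.n_frames):
        if not track.valid[i]:
            continue
        mid = track.coords[i, mid_idx, :]
        # resample the midline polyline to 24 points
        seg = np.linalg.norm(np.diff(mid, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] == 0:
            pts = np.tile(mid[0], (24, 1))
        else:
            u = np.linspace(0, s[-1], 24)
            pts = np.stack([np.interp(u, s, mid[:, 0]), np.interp(u, s, mid[:, 1])], axis=1)
        cols = nx / 2.0 + (pts[:, 0] - track.well_center[0]) / well.mm_per_px
        rows = ny / 2.0 - (pts[:, 1] - track.well_center[1]) / well.mm_per_px
        for (r, c, rad) in zip(rows, cols, taper):
            rr, cc = disk((r, c), max(rad, 1.0), shape=(ny, nx))
            frames[i, rr, cc] = fg
    return FrameStack(frames=frames, fps=track.fps, well_id=track.well_id,
                      epoch_label=track.epoch_label)


def make_training_corpus(n_per_class: int = 100, well: SimWell = SimWell(),
                         seed: int = 0, window_len: int = 60,
                         skeleton: SkeletonSpec = DEFAULT_SKELETON) -> LabeledClipSet:
    """Balanced labeled 60-frame clips cut from simulated motifs.

    Each class contributes ``n_per_class`` non-overlapping windows drawn
    from several independently seeded motifs (fresh start position,
    heading and noise per motif). Deterministic under ``seed``.
    """
    if n_per_class < 10:
        raise ValueError("need at least 10 clips per class")
    clips = []
    windows_per_motif = 5
    for ci, behavior in enumerate(BEHAVIOR_CLASSES):
        n_motifs = math.ceil(n_per_class / windows_per_motif)
        child_seeds = np.random.SeedSequence((seed, ci)).generate_state(n_motifs)
        made = 0
        for m in range(n_motifs):
            dur = windows_per_motif * window_len / well.fps
            params = motif_params(behavior, duration_s=dur)
            track, label, _ = simulate_motif(params, well, seed=int(child_seeds[m] % (2**31)),
                                             skeleton=skeleton, well_id=f"{behavior}_{m}")
            for w in range(windows_per_motif):
                if made >= n_per_class:
                    break
                s = w * window_len
                clips.append(LabeledClip(clip_id=f"{behavior}_{m}_{w}",
                                         coords=track.coords[s:s + window_len].copy(),
                                         label=label, track_id=track.well_id, start_frame=s))
                made += 1
    return LabeledClipSet(clips)
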