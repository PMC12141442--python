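import numpy as np
import pytest

from swimpose import (PoseTrack, SkeletonSpec, DEFAULT_SKELETON, SimWell,
                      simulate_motif, motif_params)


@pytest.fixture
def skeleton() -> SkeletonSpec:
    return DEFAULT_SKELETON


@pytest.fixture
def well() -> SimWell:
    return SimWell()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def straight_pose(skeleton: SkeletonSpec = DEFAULT_SKELETON, origin=(0.0, 0.0),
                  heading_deg: float = 90.0, inter_eye: float = 0.2) -> np.ndarray:
    """One straight-fish frame: midline along the heading, snout leading.

    Midline points are spaced 0.8 mm apart (4 mm body); eyes sit 0.3 mm
    behind the snout, offset half the inter-eye distance to each side.
    """
    a = np.deg2rad(heading_deg)
    u = np.array([np.cos(a), np.sin(a)])     # facing direction
    n = np.array([-np.sin(a), np.cos(a)])    # left normal
    o = np.asarray(origin, dtype=float)
    pts = {
        "snout": o,
        "rostral_trunk": o - 0.8 * u,
        "center": o - 1.6 * u,
        "caudal_trunk": o - 2.4 * u,
        "mid_tail": o - 3.2 * u,
        "caudal_fin": o - 4.0 * u,
        "eye_left": o - 0.3 * u + (inter_eye / 2) * n,
        "eye_right": o - 0.3 * u - (inter_eye / 2) * n,
    }
    return np.stack([pts[r] for r in skeleton.order])


def static_track(n_frames: int, origin=(0.0, 0.0), heading_deg: float = 90.0,
                 **track_kwargs) -> PoseTrack:
    """A perfectly still, noiseless track for gate fixtures."""
    frame = straight_pose(origin=origin, heading_deg=heading_deg)
    coords = np.tile(frame, (n_frames, 1, 1))
    return PoseTrack(coords=coords, **track_kwargs)


def moving_track(com_step_mm: float, n_frames: int, heading_deg: float = 90.0,
                 fps: float = 160.0) -> PoseTrack:
    """Constant-velocity straight swimming at com_step_mm per frame."""
    a = np.deg2rad(heading_deg)
    u = np.array([np.cos(a), np.sin(a)])
    frame = straight_pose(heading_deg=heading_deg)
    offsets = (np.arange(n_frames) * com_step_mm)[:, None] * u
    coords = frame[None] + offsets[:, None, :]
    return PoseTrack(coords=coords, fps=fps, well_radius=1e9)


@pytest.fixture
def stationary_motif():
    return simulate_motif(motif_params("stationary", 2.0), seed=11)
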