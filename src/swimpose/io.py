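"""Reading and writing pose tables, frame stacks, and label files.

Pose tables are plain CSV with a ``frame,kp0_x,kp0_y,...,kp7_x,kp7_y``
header and optional ``# key=value`` metadata comment lines; an HDF5
layout (dataset ``coords`` of shape T x 8 x 2 plus attributes) is
accepted as an equivalent. Frame stacks are multi-page grayscale TIFF.
Missing key-points are stored as empty fields / NaN and loaded as
masked frames — never imputed.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .skeleton import N_KEYPOINTS, SkeletonSpec, DEFAULT_SKELETON
from .track import PoseTrack, FrameStack, LabeledClip, LabeledClipSet, DEFAULT_FPS, DEFAULT_MM_PER_PX


class PoseFormatError(ValueError):
    """Raised for malformed pose tables, naming the offending row."""


_META_FLOAT = ("fps", "mm_per_px", "well_radius")
_EXPECTED_COLS = ["frame"] + [f"kp{k}_{ax}" for k in range(N_KEYPOINTS) for ax in ("x", "y")]


def read_pose_table(
    path: str | Path,
    skeleton: SkeletonSpec = DEFAULT_SKELETON,
    *,
    fps: float | None = None,
    mm_per_px: float | None = None,
    y_down: bool = False,
) -> PoseTrack:
    """Read a pose table (CSV or HDF5) into a :class:`PoseTrack`.

    Rows holding any missing coordinate are returned with ``valid=False``;
    coordinates are otherwise untouched except for the optional one-time
    y-axis flip (``y_down=True``) that converts raster input to the
    package's y-up frame. px input is converted to mm on load.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        track = _read_pose_h5(path)
    else:
        track = _read_pose_csv(path)
    if fps is not None:
        track.fps = float(fps)
    if mm_per_px is not None:
        track.mm_per_px = float(mm_per_px)
    if y_down:
        track.coords[..., 1] *= -1.0
        track.well_center[1] *= -1.0
    if track.unit == "px":
        track = track.to_mm()
    return track


def _parse_meta(lines: list[str]) -> dict:
    meta: dict = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if "=" not in body:
            continue
        key, _, val = body.partition("=")
        key, val = key.strip(), val.strip()
        if key in _META_FLOAT:
            meta[key] = float(val)
        elif key == "well_center":
            meta[key] = np.array([float(v) for v in val.replace("(", "").replace(")", "").split(",")])
        elif key:
            meta[key] = val
    return meta


def _read_pose_csv(path: Path) -> PoseTrack:
    comment_lines = []
    with open(path) as fh:
        text = fh.read()
    data_lines = []
    for ln in text.splitlines():
        (comment_lines if ln.startswith("#") else data_lines).append(ln)
    if not data_lines:
        raise PoseFormatError(f"{path}: no header row found")
    header = [c.strip() for c in data_lines[0].split(",")]
    if header != _EXPECTED_COLS:
        raise PoseFormatError(
            f"{path} row 1: malformed header; expected {len(_EXPECTED_COLS)} columns "
            f"'frame,kp0_x,...,kp{N_KEYPOINTS - 1}_y', got {len(header)} columns"
        )
    df = pd.read_csv(_io.StringIO("\n".join(data_lines)))
    frames = df["frame"].to_numpy()
    if len(frames) and not np.all(np.diff(frames) > 0):
        bad = int(np.flatnonzero(np.diff(frames) <= 0)[0]) + 2  # +1 for 0-base, +1 for header
        raise PoseFormatError(f"{path} row {bad + 1}: non-monotonic frame index")
    coords = df[_EXPECTED_COLS[1:]].to_numpy(dtype=float).reshape(-1, N_KEYPOINTS, 2)
    meta = _parse_meta(comment_lines)
    return _build_track(coords, meta)


def _build_track(coords: np.ndarray, meta: dict) -> PoseTrack:
    valid = np.all(np.isfinite(coords), axis=(1, 2))
    kwargs = dict(
        fps=meta.get("fps", DEFAULT_FPS),
        mm_per_px=meta.get("mm_per_px", DEFAULT_MM_PER_PX),
        unit=meta.get("unit", "mm"),
        well_id=meta.get("well_id", ""),
        epoch_label=meta.get("epoch_label", "other"),
    )
    if "well_center" in meta:
        kwargs["well_center"] = meta["well_center"]
    if "well_radius" in meta:
        kwargs["well_radius"] = meta["well_radius"]
    return PoseTrack(coords=coords, valid=valid, **kwargs)


def _read_pose_h5(path: Path) -> PoseTrack:
    with h5py.File(path, "r") as f:
        coords = np.asarray(f["coords"], dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (N_KEYPOINTS, 2):
            raise PoseFormatError(f"{path}: dataset 'coords' must be T x {N_KEYPOINTS} x 2")
        meta = {k: f.attrs[k] for k in f.attrs}
        if "well_center" in meta:
            meta["well_center"] = np.asarray(meta["well_center"], dtype=float)
        for k in _META_FLOAT:
            if k in meta:
                meta[k] = float(meta[k])
        for k in ("unit", "well_id", "epoch_label"):
            if k in meta:
                meta[k] = str(meta[k])
    return _build_track(coords, meta)


def write_pose_table(track: PoseTrack, path: str | Path, float_fmt: str = "%.9g") -> Path:
    """Write a pose table; masked frames become rows of empty fields.

    ``read_pose_table(write_pose_table(t))`` reproduces coordinates to
    the declared precision and the validity mask exactly.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _write_pose_h5(track, path)
    coords = track.coords.reshape(track.n_frames, -1)
    df = pd.DataFrame(coords, columns=_EXPECTED_COLS[1:])
    df.insert(0, "frame", np.arange(track.n_frames))
    df.loc[~track.valid, _EXPECTED_COLS[1:]] = np.nan
    with open(path, "w") as fh:
        fh.write(f"# fps={track.fps:g}\n# unit={track.unit}\n# mm_per_px={track.mm_per_px:g}\n")
        fh.write(f"# well_center={track.well_center[0]:.9g},{track.well_center[1]:.9g}\n")
        fh.write(f"# well_radius={track.well_radius:.9g}\n")
        if track.well_id:
            fh.write(f"# well_id={track.well_id}\n")
        fh.write(f"# epoch_label={track.epoch_label}\n")
        df.to_csv(fh, index=False, float_format=float_fmt, na_rep="")
    return path


def _write_pose_h5(track: PoseTrack, path: Path) -> Path:
    coords = track.coords.copy()
    coords[~track.valid] = np.nan
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=coords)
        f.attrs.update(
            fps=track.fps, unit=track.unit, mm_per_px=track.mm_per_px,
            well_center=track.well_center, well_radius=track.well_radius,
            well_id=track.well_id, epoch_label=track.epoch_label,
        )
    return path


def read_frame_stack(path: str | Path, fps: float = DEFAULT_FPS, well_id: str = "") -> FrameStack:
    """Read a multi-page grayscale TIFF (or .npy stack) into a FrameStack."""
    path = Path(path)
    if path.suffix == ".npy":
        frames = np.load(path)
    else:
        frames = tifffile.imread(path)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4 or (frames.ndim == 3 and frames.shape[-1] in (3, 4) and frames.shape[-1] != frames.shape[-2]):
        raise ValueError("RGB(A) input detected: convert frames to single-channel grayscale first")
    return FrameStack(frames=frames, fps=fps, well_id=well_id)


def write_frame_stack(stack: FrameStack, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, stack.frames)
    else:
        tifffile.imwrite(path, stack.frames)
    return path


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read a clip label CSV with columns clip_id, track_file, start_frame, label."""
    df = pd.read_csv(path, comment="#")
    required = {"clip_id", "track_file", "start_frame", "label"}
    missing = required - set(df.columns)
    if missing:
        raise PoseFormatError(f"{path}: label table missing columns {sorted(missing)}")
    return df


def write_label_table(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, index=False)
    return Path(path)


def load_labeled_clips(
    label_path: str | Path,
    window_len: int = 60,
    skeleton: SkeletonSpec = DEFAULT_SKELETON,
    base_dir: str | Path | None = None,
) -> LabeledClipSet:
    """Materialize a LabeledClipSet by cutting windows out of track files."""
    base = Path(base_dir) if base_dir is not None else Path(label_path).parent
    df = read_label_table(label_path)
    cache: dict[str, PoseTrack] = {}
    clips = []
    for row in df.itertuples(index=False):
        tf = str(row.track_file)
        if tf not in cache:
            cache[tf] = read_pose_table(base / tf, skeleton)
        track = cache[tf]
        s = int(row.start_frame)
        if s < 0 or s + window_len > track.n_frames:
            raise PoseFormatError(f"{label_path}: clip {row.clip_id} window [{s}, {s + window_len}) "
                                  f"outside track of length {track.n_frames}")
        clips.append(LabeledClip(
            clip_id=str(row.clip_id), coords=track.coords[s:s + window_len].copy(),
            label=str(row.label), track_id=tf, start_frame=s,
        ))
    return LabeledClipSet(clips)
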