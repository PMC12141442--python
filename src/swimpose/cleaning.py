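"""Track cleaning: implausible-speed, well-boundary and COM-distance gates,
followed by per-feature wavelet denoising.

The gates run in a fixed cascade (speed -> well -> COM); each gate can
only set frames invalid, never resurrect them, and a frame failing
several rules is attributed to the first gate that fires. Speeds are
gap-aware: after removals, displacement is divided by the actual elapsed
time across the gap, so a single removed frame does not fabricate a huge
apparent speed at the next one.

Denoising is discrete wavelet shrinkage (sym4 by default) with soft
universal thresholding, applied independently to each of the 16
coordinate features and to each contiguous run of valid frames — no
bridging across removed frames, which would smear discontinuities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .skeleton import SkeletonSpec, DEFAULT_SKELETON, N_KEYPOINTS
from .track import PoseTrack


@dataclass
class CleaningConfig:
    """Parameters of the cleaning cascade.

    speed_max : biologically plausible speed ceiling, mm/s (default 120).
    com_factor : key-point-to-COM distance gate in units of larval
        length (default 0.7).
    wavelet_name : orthogonal wavelet family for denoising (default sym4).
    sigma_per_feature : 16 per-feature noise scales (x and y of each of
        the 8 key-points) or "estimate" to derive them from the data.
    body_length_mm : larval length for the COM gate, or "estimate" to use
        the median midline polyline length over valid frames.
    """

    speed_max: float = 120.0
    com_factor: float = 0.7
    wavelet_name: str = "sym4"
    sigma_per_feature: np.ndarray | str = "estimate"
    body_length_mm: float | str = "estimate"
    denoise: bool = True

    def __post_init__(self) -> None:
        if self.speed_max <= 0:
            raise ValueError("speed_max must be positive")
        if self.com_factor <= 0:
            raise ValueError("com_factor must be positive")
        if self.wavelet_name not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"{self.wavelet_name!r} is not a discrete wavelet")
        if not isinstance(self.sigma_per_feature, str):
            self.sigma_per_feature = np.asarray(self.sigma_per_feature, dtype=float)
            if self.sigma_per_feature.shape != (2 * N_KEYPOINTS,):
                raise ValueError("sigma_per_feature needs one scale per coordinate feature (16)")


@dataclass
class CleaningReport:
    """Accounting of the cascade: removed-by-rule counts always sum with
    retained frames to the track length."""

    n_frames: int
    removed_speed: int = 0
    removed_well: int = 0
    removed_com: int = 0
    initially_invalid: int = 0
    retained: int = 0
    sigma_per_feature: np.ndarray | None = None
    body_length_mm: float = float("nan")
    usable: bool = True

    def check(self) -> None:
        total = self.initially_invalid + self.removed_speed + self.removed_well + self.removed_com + self.retained
        if total != self.n_frames:
            raise AssertionError("cleaning report does not conserve frames")


def compute_com(frame_coords: np.ndarray, skeleton: SkeletonSpec = DEFAULT_SKELETON) -> np.ndarray:
    """Center of mass of one frame: mean of the 6 midline key-points.

    The eye key-points are excluded — they sit lateral and rostral of the
    midline and bias the COM toward the head. Works on a single (8, 2)
    frame or a stacked (T, 8, 2) array.
    """
    frame_coords = np.asarray(frame_coords, dtype=float)
    if not np.all(np.isfinite(frame_coords)):
        raise ValueError("COM undefined on frames with missing key-points")
    return frame_coords[..., list(skeleton.midline_indices), :].mean(axis=-2)


def track_com(track: PoseTrack, skeleton: SkeletonSpec = DEFAULT_SKELETON) -> np.ndarray:
    """Per-frame COM; NaN on invalid frames."""
    out = np.full((track.n_frames, 2), np.nan)
    if track.valid.any():
        out[track.valid] = compute_com(track.coords[track.valid], skeleton)
    return out


def estimate_body_length(track: PoseTrack, skeleton: SkeletonSpec = DEFAULT_SKELETON) -> float:
    """Median over valid frames of the midline polyline length, snout to
    caudal fin."""
    if not track.valid.any():
        raise ValueError("no valid frames to estimate body length from")
    mid = track.coords[track.valid][:, list(skeleton.midline_indices), :]
    seg = np.linalg.norm(np.diff(mid, axis=1), axis=2).sum(axis=1)
    return float(np.median(seg))


def _gap_speeds(com: np.ndarray, valid: np.ndarray, fps: float) -> np.ndarray:
    """Speed at each valid frame vs the previous valid frame (NaN first)."""
    speeds = np.full(len(valid), np.nan)
    idx = np.flatnonzero(valid)
    if len(idx) < 2:
        return speeds
    d = np.linalg.norm(com[idx[1:]] - com[idx[:-1]], axis=1)
    dt = np.diff(idx) / fps
    speeds[idx[1:]] = d / dt
    return speeds


def speed_gate(track: PoseTrack, cfg: CleaningConfig, skeleton: SkeletonSpec = DEFAULT_SKELETON) -> int:
    """Invalidate frames whose gap-aware COM speed exceeds ``speed_max``.

    Sequential: when a frame is removed, the next comparison spans the
    widened gap from the last surviving frame. The first valid frame is
    never removed. Mutates the track mask in place; returns the count.
    """
    com = track_com(track, skeleton)
    idx = np.flatnonzero(track.valid)
    removed = 0
    if len(idx) < 2:
        return 0
    last = idx[0]
    for i in idx[1:]:
        dt = (i - last) / track.fps
        speed = np.linalg.norm(com[i] - com[last]) / dt
        if speed > cfg.speed_max:
            track.valid[i] = False
            removed += 1
        else:
            last = i
    return removed


def well_gate(track: PoseTrack, cfg: CleaningConfig, skeleton: SkeletonSpec = DEFAULT_SKELETON) -> int:
    """Invalidate frames whose center key-point lies strictly outside the
    circular well boundary (closed-disk convention: the boundary itself
    is retained)."""
    if track.well_center is None or track.well_radius is None or track.well_radius <= 0:
        raise ValueError("well gate requires well_center and well_radius")
    center_kp = track.coords[:, skeleton.center, :]
    dist = np.linalg.norm(center_kp - track.well_center, axis=1)
    bad = track.valid & (dist > track.well_radius)
    track.valid[bad] = False
    return int(bad.sum())


def com_gate(track: PoseTrack, cfg: CleaningConfig, skeleton: SkeletonSpec = DEFAULT_SKELETON) -> int:
    """Invalidate frames where any key-point lies more than
    ``com_factor`` x larval length from the frame's COM."""
    if not track.valid.any():
        return 0
    if isinstance(cfg.body_length_mm, str):
        body_len = estimate_body_length(track, skeleton)
    else:
        body_len = float(cfg.body_length_mm)
    com = track_com(track, skeleton)
    dist = np.linalg.norm(track.coords - com[:, None, :], axis=2)
    maxdist = np.full(track.n_frames, -np.inf)
    if track.valid.any():
        maxdist[track.valid] = dist[track.valid].max(axis=1)
    bad = track.valid & (maxdist > cfg.com_factor * body_len)
    track.valid[bad] = False
    return int(bad.sum())


def estimate_sigma(series: np.ndarray, wavelet_name: str = "sym4") -> float:
    """Robust noise scale of a 1-D series.

    Median absolute deviation of the finest-level detail coefficients
    divided by 0.6745 (the Gaussian consistency constant); smooth signal
    content lives in the approximation coefficients and coarser levels,
    so trends do not inflate the estimate.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 8:
        raise ValueError("need at least 8 samples to estimate sigma")
    _, detail = pywt.dwt(series, wavelet_name)
    return float(np.median(np.abs(detail - np.median(detail))) / 0.6745)


def average_sigma(tracks: list[PoseTrack], wavelet_name: str = "sym4") -> np.ndarray:
    """Per-feature sigma averaged across the tracks of one acquisition."""
    sig = []
    for t in tracks:
        feats = t.coords[t.valid].reshape(-1, 2 * N_KEYPOINTS)
        if feats.shape[0] >= 8:
            sig.append([estimate_sigma(feats[:, j], wavelet_name) for j in range(feats.shape[1])])
    if not sig:
        raise ValueError("no track long enough for sigma estimation")
    return np.mean(sig, axis=0)


def wavelet_denoise(series: np.ndarray, sigma: float, wavelet_name: str = "sym4") -> np.ndarray:
    """Soft-threshold wavelet shrinkage of one contiguous series.

    Universal threshold sigma * sqrt(2 ln n) applied to every detail
    level; the approximation band is untouched, so constants pass through
    exactly and sigma = 0 is the identity. Segments shorter than the
    wavelet support are returned unchanged with a warning.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    wav = pywt.Wavelet(wavelet_name)
    if n < wav.dec_len:
        warnings.warn(f"segment of length {n} shorter than wavelet support {wav.dec_len}; returned unchanged")
        return series.copy()
    if sigma == 0:
        return series.copy()
    coeffs = pywt.wavedec(series, wav, mode="symmetric")
    thr = sigma * np.sqrt(2.0 * np.log(n))
    coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    out = pywt.waverec(coeffs, wav, mode="symmetric")
    return out[:n]


def _valid_segments(valid: np.ndarray):
    """Yield (start, stop) of contiguous valid runs."""
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    yield from zip(starts, stops)


def denoise_track(track: PoseTrack, cfg: CleaningConfig) -> np.ndarray:
    """Denoise each coordinate feature on each contiguous valid segment.

    Returns the per-feature sigma actually used.
    """
    if isinstance(cfg.sigma_per_feature, str):
        sigmas = average_sigma([track], cfg.wavelet_name)
    else:
        sigmas = cfg.sigma_per_feature
    flat = track.coords.reshape(track.n_frames, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for start, stop in _valid_segments(track.valid):
            for j in range(flat.shape[1]):
                flat[start:stop, j] = wavelet_denoise(flat[start:stop, j], sigmas[j], cfg.wavelet_name)
    return sigmas


def clean_track(
    track: PoseTrack,
    cfg: CleaningConfig = CleaningConfig(),
    skeleton: SkeletonSpec = DEFAULT_SKELETON,
) -> tuple[PoseTrack, CleaningReport]:
    """Full cleaning cascade on a calibrated (mm) track.

    Gates run speed -> well -> COM, then wavelet denoising on the
    surviving contiguous segments. The input is not modified.
    """
    if track.unit != "mm":
        track = track.to_mm()
    else:
        track = track.copy()
    report = CleaningReport(n_frames=track.n_frames,
                            initially_invalid=int((~track.valid).sum()))
    report.removed_speed = speed_gate(track, cfg, skeleton)
    report.removed_well = well_gate(track, cfg, skeleton)
    report.removed_com = com_gate(track, cfg, skeleton)
    report.retained = int(track.valid.sum())
    if isinstance(cfg.body_length_mm, str):
        if track.valid.any():
            report.body_length_mm = estimate_body_length(track, skeleton)
    else:
        report.body_length_mm = float(cfg.body_length_mm)
    if report.retained == 0:
        report.usable = False
        report.check()
        return track, report
    if cfg.denoise:
        report.sigma_per_feature = denoise_track(track, cfg)
    report.check()
    return track, report


def speed_histogram(tracks: list[PoseTrack], skeleton: SkeletonSpec = DEFAULT_SKELETON,
                    bins: int = 100, log10: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Cohort speed histogram used to choose a plausibility threshold.

    Pools gap-aware instantaneous COM speeds across tracks; with
    ``log10`` the counts are binned over log10(speed in mm/s), which is
    how the cutoff is read off against the tail of anomalous jumps.
    """
    speeds = []
    for t in tracks:
        t = t.to_mm()
        s = _gap_speeds(track_com(t, skeleton), t.valid, t.fps)
        s = s[np.isfinite(s) & (s > 0)]
        speeds.append(np.log10(s) if log10 else s)
    pooled = np.concatenate(speeds) if speeds else np.array([])
    return np.histogram(pooled, bins=bins)
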