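"""Pixel-change activity metric.

For each pair of sequential grayscale frames, a pixel counts toward the
instantaneous activity A_i iff its relative change exceeds a threshold T
AND its absolute change exceeds a threshold D:

    2*|P_i - P_{i-1}| / (P_i + P_{i-1}) > T   and   |P_i - P_{i-1}| > D

Summing the per-pair counts over a 5-minute epoch yields the total
activity score used for gross-movement screening; larvae whose TP2 total
falls below 20,000 pixels are flagged for exclusion (a threshold
established for larvae that did not survive chemoconvulsant treatment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .track import FrameStack


@dataclass(frozen=True)
class ActivityParams:
    """Thresholds of the pixel-change metric.

    t_rel : relative-change threshold, unitless (default 0.1)
    d_abs : absolute-change threshold in pixel-value units (default 20)
    exclusion_threshold : total-activity cutoff in pixels (default 20,000)
    """

    t_rel: float = 0.1
    d_abs: float = 20.0
    exclusion_threshold: float = 20_000.0

    def __post_init__(self) -> None:
        if self.t_rel <= 0:
            raise ValueError("t_rel must be > 0")
        if self.d_abs < 0:
            raise ValueError("d_abs must be >= 0")
        if self.exclusion_threshold < 0:
            raise ValueError("exclusion_threshold must be >= 0")


@dataclass
class ActivityTrace:
    """Per-frame-pair pixel counts A_i and their epoch total."""

    values: np.ndarray
    well_id: str = ""
    epoch_label: str = "other"
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if np.any(self.values < 0):
            raise ValueError("activity counts must be non-negative")
        self.total = int(self.values.sum())


def frame_pair_activity(prev: np.ndarray, curr: np.ndarray, params: ActivityParams = ActivityParams()) -> int:
    """Count pixels changing between two frames by both thresholds.

    Both comparisons are strict. Pixels where ``prev + curr == 0`` have an
    undefined relative change but |delta| = 0 fails the absolute threshold,
    so they contribute 0 without special-casing. Arithmetic is carried out
    in float to avoid unsigned wraparound on the difference.
    """
    prev = np.asarray(prev, dtype=float)
    curr = np.asarray(curr, dtype=float)
    if prev.shape != curr.shape:
        raise ValueError(f"frame shape mismatch: {prev.shape} vs {curr.shape}")
    diff = np.abs(curr - prev)
    total = curr + prev
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(total > 0, 2.0 * diff / total, 0.0)
    return int(np.count_nonzero((rel > params.t_rel) & (diff > params.d_abs)))


def activity_trace(stack: FrameStack, params: ActivityParams = ActivityParams()) -> ActivityTrace:
    """Instantaneous activity for every sequential frame pair of a stack."""
    if stack.n_frames < 2:
        raise ValueError("activity trace needs at least 2 frames")
    frames = stack.frames.astype(float)
    diff = np.abs(frames[1:] - frames[:-1])
    total = frames[1:] + frames[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(total > 0, 2.0 * diff / total, 0.0)
    counts = np.count_nonzero((rel > params.t_rel) & (diff > params.d_abs), axis=(1, 2))
    return ActivityTrace(values=counts, well_id=stack.well_id, epoch_label=stack.epoch_label)


def flag_inactive(trace: ActivityTrace, params: ActivityParams = ActivityParams()) -> bool:
    """True iff the epoch total falls strictly below the exclusion cutoff.

    Intended for the second chemoconvulsant epoch (TP2), where inactivity
    indicates a larva that should be dropped from pose analysis.
    """
    return trace.total < params.exclusion_threshold
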