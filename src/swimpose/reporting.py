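"""Ethograms, per-larva epoch summaries, trajectory plot tables, and
group statistics.

An ethogram assigns one behavior class to every frame of an epoch by
majority vote over the overlapping windows covering that frame. Vote
ties resolve toward the less severe class in the fixed severity order
stationary < normal_swim < whirlpool < convulsion < posture_loss, so
overlap artifacts never inflate seizure calls; frames covered by no
window are "unscored" and class fractions are computed over scored
frames only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .track import BEHAVIOR_CLASSES
from .activity import ActivityTrace
from .kinematics import KinematicSeries
from .classify import WindowPrediction
from .windows import WindowingParams

UNSCORED = "unscored"

_SEVERITY = {c: i for i, c in enumerate(BEHAVIOR_CLASSES)}


@dataclass
class Ethogram:
    """Per-frame class labels and class fractions for one larva/epoch."""

    frame_labels: np.ndarray  # dtype=object / str, includes "unscored"
    fractions: dict[str, float]
    well_id: str = ""
    epoch_label: str = "other"

    @property
    def n_scored(self) -> int:
        return int(np.sum(self.frame_labels != UNSCORED))


def ethogram_from_predictions(predictions: list[WindowPrediction], n_frames: int,
                              params: WindowingParams = WindowingParams(),
                              well_id: str = "", epoch_label: str = "other") -> Ethogram:
    """Per-frame majority vote over the windows covering each frame."""
    if not predictions:
        raise ValueError("need at least one window prediction")
    L = params.window_len
    votes = np.zeros((n_frames, len(BEHAVIOR_CLASSES)), dtype=int)
    for p in predictions:
        stop = min(p.start_frame + L, n_frames)
        votes[p.start_frame:stop, _SEVERITY[p.label]] += 1
    covered = votes.sum(axis=1) > 0
    # argmax returns the first maximum, and columns are ordered by
    # severity, so ties resolve toward the less severe class.
    winner = votes.argmax(axis=1)
    labels = np.array([UNSCORED] * n_frames, dtype=object)
    labels[covered] = np.array(BEHAVIOR_CLASSES, dtype=object)[winner[covered]]
    n_scored = int(covered.sum())
    fractions = {c: float(np.sum(labels == c)) / n_scored if n_scored else 0.0
                 for c in BEHAVIOR_CLASSES}
    return Ethogram(frame_labels=labels, fractions=fractions,
                    well_id=well_id, epoch_label=epoch_label)


def tracking_plot_data(kin: KinematicSeries, fast_threshold: float = 50.0,
                       n_gradient_bands: int = 8) -> pd.DataFrame:
    """Trajectory table with speed bands for well-occupancy plots.

    Speeds from 0 to ``fast_threshold`` mm/s map onto a blue-to-red
    gradient of ``n_gradient_bands`` classes; anything strictly faster
    lands in a single distinct "fast" band (plotted green).
    """
    speed = kin.speed
    band = np.full(speed.shape, -1, dtype=int)
    finite = np.isfinite(speed)
    grad = finite & (speed <= fast_threshold)
    band[grad] = np.minimum((speed[grad] / fast_threshold * n_gradient_bands).astype(int),
                            n_gradient_bands - 1)
    band[finite & (speed > fast_threshold)] = n_gradient_bands
    names = np.array([f"gradient_{i}" for i in range(n_gradient_bands)] + ["fast"], dtype=object)
    label = np.where(band >= 0, names[np.clip(band, 0, n_gradient_bands)], "undefined")
    return pd.DataFrame({
        "frame": kin.frame, "x": kin.com[:, 0], "y": kin.com[:, 1],
        "speed": speed, "band": label,
    })


def epoch_summary(kin: KinematicSeries, activity: ActivityTrace | None = None) -> dict:
    """Per-larva scalar summary of one recording epoch.

    Totals and quantile summaries use valid frames only; total activity
    is reported linearly and as log10(x + 1) so zero-movement larvae stay
    finite.
    """
    theta = kin.tail_angle[np.isfinite(kin.tail_angle)]
    hc = kin.heading_change[np.isfinite(kin.heading_change)]
    d = kin.inter_eye[np.isfinite(kin.inter_eye)]
    if kin.frame.size == 0:
        raise ValueError("empty epoch")

    def q(a: np.ndarray) -> dict:
        if a.size == 0:
            return {"q25": np.nan, "median": np.nan, "q75": np.nan, "max": np.nan}
        return {"q25": float(np.percentile(a, 25)), "median": float(np.median(a)),
                "q75": float(np.percentile(a, 75)), "max": float(a.max())}

    out = {
        "well_id": kin.well_id,
        "epoch_label": kin.epoch_label,
        "total_distance_m": kin.total_distance_m,
        "max_speed_mm_s": kin.max_speed,
        "mean_inter_eye_mm": float(d.mean()) if d.size else np.nan,
        "tail_angle_deg": q(theta),
        "abs_heading_change_deg": q(np.abs(hc)),
    }
    if activity is not None:
        out["total_activity"] = activity.total
        out["log10_total_activity"] = float(np.log10(activity.total + 1))
    return out


@dataclass
class GroupComparison:
    """Two-group comparison with normality screens alongside."""

    metric: str
    design: str  # "paired" | "unpaired"
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    test_name: str
    shapiro_p: tuple[float, float]
    ks_p: tuple[float, float]


def _normality(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    if len(values) < 3 or np.ptp(values) == 0:
        return (np.nan, np.nan)
    sw = stats.shapiro(values).pvalue
    z = (values - values.mean()) / values.std(ddof=1)
    ks = stats.kstest(z, "norm").pvalue
    return (float(sw), float(ks))


def compare_groups(values_a: np.ndarray, values_b: np.ndarray,
                   design: str = "paired", metric: str = "") -> GroupComparison:
    """Wilcoxon matched-pairs signed-rank test (paired) or two-sample
    t-test (unpaired), two-tailed, with Shapiro-Wilk and
    Kolmogorov-Smirnov normality screens reported alongside.

    Identical paired vectors (all differences zero) return p = 1 by
    convention: there is no evidence of a shift.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if design == "paired":
        if a.shape != b.shape:
            raise ValueError("paired design requires equal-length matched vectors")
        if np.all(a == b):
            statistic, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(a, b, alternative="two-sided")
            statistic, p = float(res.statistic), float(res.pvalue)
        test_name = "wilcoxon_signed_rank"
    elif design == "unpaired":
        res = stats.ttest_ind(a, b, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
        test_name = "t_test_unpaired"
    else:
        raise ValueError("design must be 'paired' or 'unpaired'")
    return GroupComparison(metric=metric, design=design, statistic=statistic,
                           p_value=p, n_a=len(a), n_b=len(b), test_name=test_name,
                           shapiro_p=_normality(a), ks_p=_normality(b))
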