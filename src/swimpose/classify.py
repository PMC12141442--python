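"""Supervised behavior classification over aligned pose windows.

Feature vectors (length 960) are normalized by subtracting the
per-feature mean and dividing by the per-feature maximum absolute value
after centering, then projected onto the principal components retaining
95% of cumulative variance. Both the normalizer and the projection are
fitted on the training split only and re-applied unchanged to the test
split, so test accuracy is uncontaminated.

Three algorithms are supported: random forest (1000 trees), k-nearest
neighbors, and a support-vector classifier capped at 1000 optimizer
iterations. Evaluation reports the confusion matrix (rows = true class,
columns = predicted), per-class precision TP/(TP+FP) and recall
TP/(TP+FN), their macro averages, overall accuracy, and an F1 score
computed literally from the confusion-matrix sums

    F1 = sum_i M_ii / (sum_i M_ii + 1/2 [sum_{i!=j} M_ij + sum_{i!=j} M_ji])

which for single-label multiclass matrices is algebraically equal to
overall accuracy trace(M)/sum(M) — both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .skeleton import SkeletonSpec, DEFAULT_SKELETON
from .track import PoseTrack, LabeledClip, LabeledClipSet, BEHAVIOR_CLASSES
from .windows import WindowingParams, make_windows, egocentric_align, flatten_features

ALGORITHMS = ("random_forest", "k_nearest", "support_vector")


@dataclass
class FeaturePipeline:
    """Mean/max normalizer + PCA projection fitted on training data only."""

    mean: np.ndarray = None  # type: ignore[assignment]
    scale: np.ndarray = None  # type: ignore[assignment]
    components: np.ndarray = None  # type: ignore[assignment]
    explained_variance_ratio: np.ndarray = None  # type: ignore[assignment]
    n_components: int = 0
    variance_target: float = 0.95
    degenerate: bool = False  # all-identical training set: no informative axes

    @property
    def fitted(self) -> bool:
        return self.mean is not None


def clip_features(clip_coords: np.ndarray, skeleton: SkeletonSpec = DEFAULT_SKELETON) -> np.ndarray:
    """Egocentrically align one raw window and flatten it to a vector."""
    return flatten_features(egocentric_align(clip_coords, skeleton))


def clipset_features(clips: LabeledClipSet | list[LabeledClip],
                     skeleton: SkeletonSpec = DEFAULT_SKELETON) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and label array for a clip set."""
    X = np.stack([clip_features(c.coords, skeleton) for c in clips])
    y = np.array([c.label for c in clips])
    return X, y


def fit_pipeline(train_vectors: np.ndarray, variance_target: float = 0.95) -> FeaturePipeline:
    """Fit the normalizer and PCA basis on training vectors only.

    Zero-variance features get a unit divisor. The projection keeps the
    minimal number of leading components whose cumulative explained
    variance reaches ``variance_target``; a degenerate training set (all
    vectors identical) is flagged and projected to zero components.
    """
    X = np.asarray(train_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("training set must be a non-empty (n, p) matrix")
    mean = X.mean(axis=0)
    centered = X - mean
    scale = np.abs(centered).max(axis=0)
    scale[scale == 0] = 1.0
    Z = centered / scale
    if X.shape[0] < 2 or not np.any(Z):
        return FeaturePipeline(mean=mean, scale=scale,
                               components=np.empty((0, X.shape[1])),
                               explained_variance_ratio=np.empty(0),
                               n_components=0, variance_target=variance_target,
                               degenerate=True)
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    pca.fit(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(cum))
    return FeaturePipeline(mean=mean, scale=scale,
                           components=pca.components_[:k].copy(),
                           explained_variance_ratio=pca.explained_variance_ratio_[:k].copy(),
                           n_components=k, variance_target=variance_target)


def transform(pipeline: FeaturePipeline, vectors: np.ndarray) -> np.ndarray:
    """Apply the fitted normalizer + projection (train and test alike)."""
    if not pipeline.fitted:
        raise ValueError("pipeline is not fitted")
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    Z = (X - pipeline.mean) / pipeline.scale
    return Z @ pipeline.components.T


def balanced_test_split(clips: LabeledClipSet, test_frac: float = 0.10,
                        seed: int = 0) -> tuple[LabeledClipSet, LabeledClipSet]:
    """Per-class 90/10 split with a class-balanced test set.

    Within each class, ``round(test_frac * n)`` clips (at least 1) are
    drawn at random for the test pool; the balanced test set then takes
    the minimum per-class pool size from every class, and surplus test
    clips return to the training set. Deterministic under ``seed``.
    """
    by_class = clips.by_class()
    missing = [c for c in BEHAVIOR_CLASSES if c not in by_class]
    for cls, members in by_class.items():
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 clips")
    rng = np.random.default_rng(seed)
    pools: dict[str, list] = {}
    trains: dict[str, list] = {}
    for cls in sorted(by_class):
        members = by_class[cls]
        order = rng.permutation(len(members))
        n_test = max(1, round(test_frac * len(members)))
        pools[cls] = [members[i] for i in order[:n_test]]
        trains[cls] = [members[i] for i in order[n_test:]]
    n_bal = min(len(p) for p in pools.values())
    test, train = [], []
    for cls in sorted(by_class):
        test.extend(pools[cls][:n_bal])
        train.extend(trains[cls])
        train.extend(pools[cls][n_bal:])  # surplus returns to training
    return clips.subset(train), clips.subset(test)


@dataclass
class BehaviorModel:
    """A fitted classifier plus the feature pipeline it was trained with."""

    algorithm: str
    estimator: object
    pipeline: FeaturePipeline
    classes: tuple[str, ...] = BEHAVIOR_CLASSES
    skeleton: SkeletonSpec = field(default_factory=lambda: DEFAULT_SKELETON)

    def predict_features(self, vectors: np.ndarray) -> np.ndarray:
        return self.estimator.predict(transform(self.pipeline, vectors))


def _make_estimator(algorithm: str, hyperparams: dict | None, seed: int):
    hp = dict(hyperparams or {})
    if algorithm == "random_forest":
        hp.setdefault("n_estimators", 1000)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if algorithm == "k_nearest":
        hp.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**hp)
    if algorithm == "support_vector":
        hp.setdefault("max_iter", 1000)
        hp.setdefault("kernel", "rbf")
        return SVC(random_state=seed, **hp)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def train_classifier(train: LabeledClipSet, pipeline: FeaturePipeline,
                     algorithm: str = "random_forest",
                     hyperparams: dict | None = None, seed: int = 0,
                     skeleton: SkeletonSpec = DEFAULT_SKELETON) -> BehaviorModel:
    """Train one of the three classifiers on projected training features."""
    if not pipeline.fitted:
        raise ValueError("fit the feature pipeline before training")
    X, y = clipset_features(train, skeleton)
    est = _make_estimator(algorithm, hyperparams, seed)
    est.fit(transform(pipeline, X), y)
    return BehaviorModel(algorithm=algorithm, estimator=est, pipeline=pipeline, skeleton=skeleton)


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     classes: tuple[str, ...] = BEHAVIOR_CLASSES) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    index = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        M[index[str(t)], index[str(p)]] += 1
    return M


def eq5_f1(M: np.ndarray) -> float:
    """F1 from the confusion-matrix sums (diagonal over diagonal plus half
    the two symmetric off-diagonal sums)."""
    M = np.asarray(M, dtype=float)
    diag = np.trace(M)
    off = M.sum() - diag
    off_t = M.T.sum() - diag
    denom = diag + 0.5 * (off + off_t)
    return float(diag / denom) if denom > 0 else float("nan")


@dataclass
class EvalReport:
    """Confusion matrix and the derived per-class / macro metrics."""

    confusion: np.ndarray
    classes: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    per_class_accuracy: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    f1: float          # literal confusion-sum form above
    accuracy: float    # trace / total
    absent_classes: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "per_class_accuracy": self.per_class_accuracy.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "absent_classes": list(self.absent_classes),
        }


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                         classes: tuple[str, ...] = BEHAVIOR_CLASSES) -> EvalReport:
    M = confusion_matrix(y_true, y_pred, classes)
    tp = np.diag(M).astype(float)
    fp = M.sum(axis=0) - tp
    fn = M.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        recall = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        per_class_f1 = np.where(np.isfinite(precision) & np.isfinite(recall) & (precision + recall > 0),
                                2 * precision * recall / (precision + recall), np.nan)
    support = M.sum(axis=1)
    absent = tuple(c for c, s in zip(classes, support) if s == 0)
    present = support > 0
    total = M.sum()
    return EvalReport(
        confusion=M, classes=classes,
        precision=precision, recall=recall,
        per_class_accuracy=np.where(present, tp / np.maximum(support, 1), np.nan),
        macro_precision=float(np.nanmean(precision[present])),
        macro_recall=float(np.nanmean(recall[present])),
        macro_f1=float(np.nanmean(per_class_f1[present])),
        f1=eq5_f1(M),
        accuracy=float(np.trace(M) / total) if total else float("nan"),
        absent_classes=absent,
    )


def evaluate(model: BehaviorModel, test: LabeledClipSet) -> EvalReport:
    """Evaluate a trained model on a (balanced) held-out clip set."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    X, y = clipset_features(test, model.skeleton)
    return evaluate_predictions(y, model.predict_features(X), model.classes)


#: Small random-forest hyperparameter grid searched by tune_random_forest.
FOREST_GRID = (
    {"max_features": "sqrt", "min_samples_leaf": 1},
    {"max_features": "sqrt", "min_samples_leaf": 3},
    {"max_features": 0.2, "min_samples_leaf": 1},
    {"max_features": 0.2, "min_samples_leaf": 3},
)


def tune_random_forest(train: LabeledClipSet, pipeline: FeaturePipeline,
                       seed: int = 0, grid: tuple[dict, ...] = FOREST_GRID,
                       val_frac: float = 0.2,
                       skeleton: SkeletonSpec = DEFAULT_SKELETON) -> BehaviorModel:
    """Pick forest hyperparameters on an internal validation split, then
    refit the winner on the full training set with 1000 trees.

    The grid is deliberately small and fixed; each candidate is scored by
    validation accuracy with 300 trees, ties going to the earlier entry.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train))
    n_val = max(1, int(round(val_frac * len(train))))
    clips = list(train)
    val = train.subset([clips[i] for i in order[:n_val]])
    fit = train.subset([clips[i] for i in order[n_val:]])
    Xv, yv = clipset_features(val, skeleton)
    best_hp, best_acc = grid[0], -1.0
    for hp in grid:
        model = train_classifier(fit, pipeline, "random_forest",
                                 hyperparams={**hp, "n_estimators": 300},
                                 seed=seed, skeleton=skeleton)
        acc = float(np.mean(model.predict_features(Xv) == yv))
        if acc > best_acc:
            best_hp, best_acc = hp, acc
    return train_classifier(train, pipeline, "random_forest",
                            hyperparams={**best_hp, "n_estimators": 1000},
                            seed=seed, skeleton=skeleton)


@dataclass
class WindowPrediction:
    start_frame: int
    label: str


def predict_track(model: BehaviorModel, track: PoseTrack,
                  params: WindowingParams = WindowingParams()) -> list[WindowPrediction]:
    """Classify every retainable window of a cleaned track.

    Returns one prediction per window, time-stamped by start frame; a
    track too short (or too gappy) for a single window yields an empty
    list.
    """
    wins = [w for w in make_windows(track, params)]
    feats = []
    kept = []
    for w in wins:
        try:
            feats.append(clip_features(w.coords, model.skeleton))
            kept.append(w)
        except ValueError:
            continue  # degenerate heading in first frame: window rejected
    if not kept:
        import warnings
        warnings.warn("no retainable windows in track; empty prediction")
        return []
    labels = model.predict_features(np.stack(feats))
    return [WindowPrediction(start_frame=w.start_frame, label=str(l)) for w, l in zip(kept, labels)]
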