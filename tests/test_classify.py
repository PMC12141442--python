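import numpy as np
import pytest

from swimpose import (LabeledClip, LabeledClipSet, fit_pipeline, transform,
                      balanced_test_split, train_classifier, evaluate,
                      evaluate_predictions, confusion_matrix, eq5_f1,
                      predict_track, WindowingParams, make_training_corpus,
                      clipset_features, simulate_motif, simulate_epoch,
                      motif_params, BEHAVIOR_CLASSES, ALGORITHMS)


# ---------------------------------------------------------------- pipeline

def test_pipeline_degenerate_training_set():
    X = np.tile(np.arange(6.0), (4, 1))
    pl = fit_pipeline(X)
    assert pl.degenerate and pl.n_components == 0
    np.testing.assert_allclose(transform(pl, X), np.zeros((4, 0)))


def test_pipeline_keeps_dominant_component():
    rng = np.random.default_rng(0)
    # strongly correlated features: one diagonal direction carries ~99%
    # of the variance, so a single component reaches the 95% target
    t = rng.normal(0, 10, 400)
    X = np.stack([t + rng.normal(0, 0.5, 400), t + rng.normal(0, 0.5, 400)], axis=1)
    pl = fit_pipeline(X)
    assert pl.n_components == 1
    assert pl.explained_variance_ratio[0] >= 0.95


def test_pipeline_zero_variance_feature_unit_divisor():
    X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
    pl = fit_pipeline(X)
    assert pl.scale[1] == 1.0


def test_pipeline_same_parameters_on_train_and_test(rng):
    X_train = rng.normal(size=(50, 16))
    X_test = rng.normal(size=(10, 16))
    pl = fit_pipeline(X_train)
    # transform is a pure function of the fitted parameters
    np.testing.assert_array_equal(transform(pl, X_test), transform(pl, X_test))
    combined = transform(pl, np.vstack([X_train, X_test]))
    np.testing.assert_array_equal(combined[50:], transform(pl, X_test))


def test_pipeline_fitted_on_train_only(rng):
    X_train = rng.normal(size=(40, 16))
    pl1 = fit_pipeline(X_train)
    pl2 = fit_pipeline(X_train)  # test data never enters the fit
    np.testing.assert_array_equal(pl1.mean, pl2.mean)
    np.testing.assert_array_equal(pl1.components, pl2.components)


def test_pipeline_empty_training_set_rejected():
    with pytest.raises(ValueError):
        fit_pipeline(np.empty((0, 8)))


# ---------------------------------------------------------------- split

def _toy_clips(counts: dict[str, int]) -> LabeledClipSet:
    rng = np.random.default_rng(1)
    clips = []
    for cls, n in counts.items():
        for i in range(n):
            clips.append(LabeledClip(clip_id=f"{cls}{i}", label=cls,
                                     coords=rng.normal(size=(60, 8, 2)),
                                     track_id=cls, start_frame=i * 60))
    return LabeledClipSet(clips)


def test_balanced_split_equal_classes():
    clips = _toy_clips({c: 100 for c in BEHAVIOR_CLASSES})
    train, test = balanced_test_split(clips, seed=0)
    assert len(test) == 50 and len(train) == 450
    counts = {c: test.labels().count(c) for c in BEHAVIOR_CLASSES}
    assert all(v == 10 for v in counts.values())


def test_balanced_split_surplus_returns_to_train():
    clips = _toy_clips({c: 200 if c == "stationary" else 100 for c in BEHAVIOR_CLASSES})
    train, test = balanced_test_split(clips, seed=0)
    # min class test pool = 10, stationary surplus of 10 returns to train
    assert test.labels().count("stationary") == 10
    assert len(train) == 600 - 50
    assert set(c.clip_id for c in train).isdisjoint(c.clip_id for c in test)


def test_balanced_split_deterministic():
    clips = _toy_clips({c: 40 for c in BEHAVIOR_CLASSES})
    t1 = balanced_test_split(clips, seed=9)
    t2 = balanced_test_split(clips, seed=9)
    assert [c.clip_id for c in t1[1]] == [c.clip_id for c in t2[1]]
    t3 = balanced_test_split(clips, seed=10)
    assert [c.clip_id for c in t3[1]] != [c.clip_id for c in t1[1]]


def test_balanced_split_tiny_class_rejected():
    clips = _toy_clips({**{c: 20 for c in BEHAVIOR_CLASSES}, "posture_loss": 1})
    with pytest.raises(ValueError, match="fewer than 2"):
        balanced_test_split(clips, seed=0)


# ---------------------------------------------------------------- metrics

def test_perfect_confusion_metrics():
    rep = evaluate_predictions(["stationary"] * 5 + ["whirlpool"] * 5,
                               ["stationary"] * 5 + ["whirlpool"] * 5)
    assert rep.f1 == rep.accuracy == 1.0
    assert rep.macro_precision == rep.macro_recall == 1.0


def test_precision_recall_hand_values():
    # class a: TP=8, FP=2 -> precision 0.8; TP=8, FN=8 -> recall 0.5
    y_true = ["stationary"] * 16 + ["whirlpool"] * 12
    y_pred = (["stationary"] * 8 + ["whirlpool"] * 8
              + ["stationary"] * 2 + ["whirlpool"] * 10)
    rep = evaluate_predictions(y_true, y_pred)
    i = rep.classes.index("stationary")
    assert rep.precision[i] == pytest.approx(0.8)
    assert rep.recall[i] == pytest.approx(0.5)


def test_f1_hand_value_from_confusion_sums():
    M = np.array([[5, 1], [1, 5]])
    # 10 / (10 + 0.5*(2 + 2))
    assert eq5_f1(M) == pytest.approx(10 / 12)


def test_f1_identity_equals_accuracy_on_random_matrices(rng):
    for _ in range(1000):
        M = rng.integers(0, 50, size=(5, 5))
        if M.sum() == 0:
            continue
        assert abs(eq5_f1(M) - np.trace(M) / M.sum()) < 1e-12


def test_confusion_orientation_rows_true():
    M = confusion_matrix(["stationary"], ["convulsion"])
    i = BEHAVIOR_CLASSES.index("stationary")
    j = BEHAVIOR_CLASSES.index("convulsion")
    assert M[i, j] == 1 and M[j, i] == 0


def test_absent_class_flagged():
    rep = evaluate_predictions(["stationary"] * 4, ["stationary"] * 4)
    assert "whirlpool" in rep.absent_classes


# ---------------------------------------------------------------- training

@pytest.fixture(scope="module")
def small_corpus():
    return make_training_corpus(n_per_class=20, seed=3)


def test_all_algorithms_fit_separable_data():
    # two classes of clips differing in body scale: cleanly separable
    # even after egocentric alignment (which removes pose, not size)
    from conftest import straight_pose
    rng = np.random.default_rng(2)
    clips = []
    for i in range(40):
        scale = 1.0 if i % 2 == 0 else 2.0
        label = "stationary" if i % 2 == 0 else "whirlpool"
        frame = straight_pose() * scale
        coords = np.tile(frame, (60, 1, 1)) + rng.normal(0, 0.01, size=(60, 8, 2))
        clips.append(LabeledClip(clip_id=f"c{i}", coords=coords, label=label,
                                 track_id="toy", start_frame=i * 60))
    toy = LabeledClipSet(clips)
    X, y = clipset_features(toy)
    pl = fit_pipeline(X)
    for algo in ALGORITHMS:
        hp = {"n_estimators": 100} if algo == "random_forest" else None
        model = train_classifier(toy, pl, algorithm=algo, hyperparams=hp, seed=3)
        train_acc = np.mean(model.predict_features(X) == y)
        assert train_acc == 1.0, f"{algo} should fit separable training data"


def test_unknown_algorithm_rejected(small_corpus):
    X, _ = clipset_features(small_corpus)
    pl = fit_pipeline(X)
    with pytest.raises(ValueError, match="unknown algorithm"):
        train_classifier(small_corpus, pl, algorithm="boosted_stump")


def test_same_seed_identical_predictions(small_corpus):
    train, test = balanced_test_split(small_corpus, seed=4)
    X, _ = clipset_features(train)
    pl = fit_pipeline(X)
    Xt, _ = clipset_features(test)
    m1 = train_classifier(train, pl, hyperparams={"n_estimators": 100}, seed=5)
    m2 = train_classifier(train, pl, hyperparams={"n_estimators": 100}, seed=5)
    np.testing.assert_array_equal(m1.predict_features(Xt), m2.predict_features(Xt))


def test_label_permutation_reaches_chance_level(small_corpus):
    rng = np.random.default_rng(6)
    train, test = balanced_test_split(small_corpus, seed=6)
    permuted = LabeledClipSet([
        LabeledClip(clip_id=c.clip_id, coords=c.coords, label=lbl,
                    track_id=c.track_id, start_frame=c.start_frame)
        for c, lbl in zip(train, rng.permutation(train.labels()))
    ])
    X, _ = clipset_features(permuted)
    pl = fit_pipeline(X)
    model = train_classifier(permuted, pl, hyperparams={"n_estimators": 200}, seed=6)
    rep = evaluate(model, test)
    assert rep.accuracy < 0.5  # far below the genuine-label performance


# ---------------------------------------------------------------- prediction

def _quick_model(seed=12):
    corpus = make_training_corpus(n_per_class=20, seed=seed)
    X, _ = clipset_features(corpus)
    pl = fit_pipeline(X)
    return train_classifier(corpus, pl, hyperparams={"n_estimators": 200}, seed=seed)


def test_predict_track_stationary(stationary_motif):
    model = _quick_model()
    track, _, _ = stationary_motif
    preds = predict_track(model, track, WindowingParams(stride=60))
    assert preds and all(p.label == "stationary" for p in preds)


def test_predict_track_changepoint_localized():
    model = _quick_model()
    track, labels, _ = simulate_epoch([("stationary", 2.0), ("whirlpool", 2.0)], seed=13)
    preds = predict_track(model, track, WindowingParams(stride=60))
    pred_labels = [p.label for p in preds]
    switch = next(i for i, l in enumerate(pred_labels) if l == "whirlpool")
    true_switch_frame = 2.0 * 160
    assert abs(preds[switch].start_frame - true_switch_frame) <= 2 * 60


def test_predict_track_too_short_returns_empty():
    track, _, _ = simulate_motif(motif_params("stationary", 59 / 160), seed=14)
    model = _quick_model()
    with pytest.warns(UserWarning, match="no retainable"):
        assert predict_track(model, track) == []
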