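"""Fold plans, metrics arithmetic, CI aggregation, classifier contract."""

import numpy as np
import pytest

from swinbeat.classify import SwinClassifier
from swinbeat.evaluate import (
    aggregate,
    confusion_matrix,
    crossval_images,
    evaluate,
    evaluate_from_confusion,
    make_folds,
)


# ---------------------------------------------------------------------------
# Fold plans
# ---------------------------------------------------------------------------

def test_intra_folds_partition():
    y = np.repeat(list("NSVFQ"), 20)
    plan = make_folds(y, "intra", k=10, seed=3)
    all_idx = np.sort(np.concatenate(plan.folds))
    np.testing.assert_array_equal(all_idx, np.arange(len(y)))
    plan2 = make_folds(y, "intra", k=10, seed=3)
    for a, b in zip(plan.folds, plan2.folds):
        np.testing.assert_array_equal(a, b)


def test_inter_folds_subject_disjoint_many_seeds():
    rng = np.random.default_rng(0)
    n = 300
    subjects = rng.integers(0, 25, n).astype(str)
    y = rng.integers(0, 5, n)
    for seed in range(100):
        plan = make_folds(y, "inter", k=10, seed=seed, subjects=subjects)
        all_idx = np.sort(np.concatenate(plan.folds))
        np.testing.assert_array_equal(all_idx, np.arange(n))
        for i in range(10):
            val_subj = set(subjects[plan.folds[i]])
            train_subj = set(subjects[plan.train_indices(i)])
            assert not val_subj & train_subj


def test_inter_folds_invariant_to_beat_order():
    """Which subjects co-occur in a fold depends only on the subject set."""
    rng = np.random.default_rng(1)
    subjects = np.repeat([f"s{i}" for i in range(12)], 10)
    y = np.zeros(len(subjects))
    plan = make_folds(y, "inter", k=10, seed=5, subjects=subjects)
    perm = rng.permutation(len(subjects))
    plan2 = make_folds(y[perm], "inter", k=10, seed=5,
                       subjects=subjects[perm])
    groups1 = [frozenset(subjects[f]) for f in plan.folds]
    groups2 = [frozenset(subjects[perm][f]) for f in plan2.folds]
    assert groups1 == groups2


def test_fold_errors():
    with pytest.raises(ValueError):
        make_folds(np.zeros(5), "intra", k=10)
    with pytest.raises(ValueError):
        make_folds(np.zeros(50), "inter", k=10,
                   subjects=np.repeat(["a", "b"], 25))
    with pytest.raises(ValueError):
        make_folds(np.zeros(50), "inter", k=10)
    with pytest.raises(ValueError):
        make_folds(np.zeros(50), "bogus")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def test_perfect_predictions_all_ones():
    y = np.array(list("NSVFQ") * 4)
    proba = np.zeros((len(y), 5))
    classes = list("NSVFQ")
    for i, label in enumerate(y):
        proba[i, classes.index(label)] = 1.0
    r = evaluate(y, proba, classes)
    for m in ("accuracy", "precision", "sensitivity", "specificity",
              "f1", "auc"):
        assert getattr(r, m) == pytest.approx(1.0)
    assert np.trace(r.confusion) == len(y)


def test_hand_computed_confusion_metrics():
    """[[8,2],[3,7]]: accuracy 0.75, class-0 precision 8/11, recall 0.8."""
    cm = np.array([[8, 2], [3, 7]])
    r = evaluate_from_confusion(cm, ["a", "b"])
    assert r.accuracy == pytest.approx(0.75)
    assert r.per_class["a"]["precision"] == pytest.approx(8 / 11)
    assert r.per_class["a"]["sensitivity"] == pytest.approx(0.8)
    assert r.per_class["a"]["specificity"] == pytest.approx(0.7)
    f1a = 2 * (8 / 11) * 0.8 / (8 / 11 + 0.8)
    assert r.per_class["a"]["f1"] == pytest.approx(f1a)
    # row sums equal per-class test counts
    np.testing.assert_array_equal(r.confusion.sum(axis=1), [10, 10])


def test_random_scores_auc_near_half():
    rng = np.random.default_rng(7)
    n = 2000
    y = rng.integers(0, 2, n).astype(str)
    proba = rng.random((n, 2))
    proba /= proba.sum(axis=1, keepdims=True)
    r = evaluate(y, proba, ["0", "1"])
    assert abs(r.auc - 0.5) < 0.05


def test_absent_class_excluded_from_macro():
    y = np.array(["a"] * 6 + ["b"] * 4)
    proba = np.zeros((10, 3))
    proba[:6, 0] = 1.0
    proba[6:, 1] = 1.0
    r = evaluate(y, proba, ["a", "b", "c"])
    assert np.isnan(r.per_class["c"]["sensitivity"])
    assert r.sensitivity == pytest.approx(1.0)  # macro over a, b only


def test_confusion_count_conservation():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 3, 57).astype(str)
    pred = rng.integers(0, 3, 57).astype(str)
    cm = confusion_matrix(y, pred, ["0", "1", "2"])
    assert cm.sum() == 57
    micro = np.trace(cm) / cm.sum()
    assert micro == pytest.approx(np.mean(y == pred))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _dummy_report(acc):
    cm = np.array([[10, 0], [0, 10]])
    r = evaluate_from_confusion(cm, ["a", "b"], auc=acc)
    r.accuracy = r.precision = r.sensitivity = r.specificity = r.f1 = acc
    return r


def test_aggregate_closed_form_ci():
    agg = aggregate([_dummy_report(0.9), _dummy_report(1.0)])
    assert agg.accuracy == pytest.approx(0.95)
    half = 1.96 * np.std([0.9, 1.0], ddof=1) / np.sqrt(2)
    assert agg.ci["accuracy"][0] == pytest.approx(0.95 - half)
    assert agg.ci["accuracy"][1] == pytest.approx(min(1.0, 0.95 + half))


def test_aggregate_identical_folds_zero_width():
    agg = aggregate([_dummy_report(0.8)] * 5)
    lo, hi = agg.ci["f1"]
    assert lo == pytest.approx(0.8) and hi == pytest.approx(0.8)


def test_aggregate_bounds_clipped():
    agg = aggregate([_dummy_report(0.01), _dummy_report(0.99)])
    for lo, hi in agg.ci.values():
        assert 0.0 <= lo <= hi <= 1.0
    with pytest.raises(ValueError):
        aggregate([_dummy_report(0.5)])


# ---------------------------------------------------------------------------
# Classifier contract
# ---------------------------------------------------------------------------

def test_classifier_sklearn_contract(rng):
    from sklearn.base import clone

    clf = SwinClassifier(epochs=2, batch_size=8, seed=0)
    params = clf.get_params()
    assert params["epochs"] == 2
    clone(clf)  # must be clonable
    X = rng.random((10, 32, 32, 3)).astype(np.float32)
    y = np.array(list("NSVFQ") * 2)
    clf.fit(X, y)
    assert sorted(clf.classes_) == sorted(set(y))
    proba = clf.predict_proba(X)
    assert proba.shape == (10, 5)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
    assert set(clf.predict(X)) <= set(y)
    assert len(clf.loss_curve_) == 2


def test_classifier_determinism(rng):
    X = rng.random((8, 32, 32, 3)).astype(np.float32)
    y = np.array(list("NSVF") * 2)
    p1 = SwinClassifier(epochs=2, seed=3).fit(X, y).predict_proba(X)
    p2 = SwinClassifier(epochs=2, seed=3).fit(X, y).predict_proba(X)
    np.testing.assert_array_equal(p1, p2)


def test_classifier_single_class_loss_vanishes(rng):
    X = rng.random((6, 32, 32, 3)).astype(np.float32)
    y = np.array(["N"] * 6)
    clf = SwinClassifier(epochs=3, seed=0).fit(X, y)
    assert clf.loss_curve_[-1] < 1e-6  # one class: loss is trivially ~0


def test_classifier_input_validation(rng):
    clf = SwinClassifier(epochs=1)
    with pytest.raises(ValueError):
        clf.fit(rng.random((4, 16, 16, 3)), ["a"] * 4)
    with pytest.raises(ValueError):
        clf.fit(rng.random((4, 32, 32, 3)), ["a"] * 3)
    with pytest.raises(ValueError):
        clf.fit(np.empty((0, 32, 32, 3)), [])


def test_crossval_images_smoke(rng):
    X = rng.random((40, 32, 32, 3)).astype(np.float32)
    y = np.array(list("NSVFQ") * 8)
    agg, reports = crossval_images(
        X, y, SwinClassifier(epochs=1, seed=0), paradigm="intra", k=4, seed=0)
    assert len(reports) == 4
    assert agg.confusion.sum() == 40
    assert 0.0 <= agg.accuracy <= 1.0
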