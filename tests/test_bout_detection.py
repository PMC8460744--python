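"""Gaussian Bayes gait classifier, label smoothing, bout extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from realgait.bout_detection import (
    DetectorModel,
    classify_seconds,
    detection_performance,
    labels_to_bouts,
    postprocess_labels,
    train_detector,
)

FEATURES = ["intensity", "periodicity", "posture", "noisiness"]


def _frame(X):
    return pd.DataFrame(X, columns=FEATURES)


def _toy_data(n=400, seed=0):
    rng = np.random.default_rng(seed)
    gait = rng.normal([0.4, 0.8, 70, 0.1], [0.1, 0.1, 10, 0.05], (n, 4))
    rest = rng.normal([0.02, 0.2, 15, 0.4], [0.01, 0.1, 10, 0.15], (n, 4))
    X = np.vstack([rest, gait])
    y = np.r_[np.zeros(n), np.ones(n)].astype(int)
    return _frame(X), y


def test_train_and_separate_classes():
    X, y = _toy_data()
    model = train_detector(X, y)
    acc = (classify_seconds(model, X) == y).mean()
    assert acc > 0.95  # classes built to be Bayes-separable
    assert model.priors == pytest.approx([0.5, 0.5])


def test_train_errors():
    X, y = _toy_data()
    with pytest.raises(ValueError):
        train_detector(X, np.ones(len(X), int))
    Xz = X.copy()
    Xz["posture"] = 1.0
    with pytest.raises(ValueError, match="posture"):
        train_detector(Xz, y)


def test_train_duplication_invariance():
    X, y = _toy_data()
    m1 = train_detector(X, y)
    m2 = train_detector(pd.concat([X, X], ignore_index=True), np.r_[y, y])
    assert np.allclose(m1.means, m2.means)
    assert np.allclose(m1.variances, m2.variances, rtol=1e-2)


def test_classify_posterior_oracle():
    """3-second toy series against a brute-force posterior computation."""
    from scipy.stats import norm

    model = DetectorModel(
        feature_names=tuple(FEATURES),
        means=[[0.0, 0.2, 20, 0.4], [0.4, 0.8, 70, 0.1]],
        variances=[[0.01, 0.04, 100, 0.04], [0.02, 0.01, 64, 0.01]],
        priors=[0.7, 0.3],
    )
    X = _frame([[0.35, 0.75, 65, 0.12], [0.05, 0.25, 25, 0.35], [0.2, 0.5, 45, 0.2]])
    pred = classify_seconds(model, X)
    for i in range(3):
        post = []
        for c in (0, 1):
            lik = np.prod(
                norm.pdf(
                    X.iloc[i].to_numpy(),
                    model.means[c],
                    np.sqrt(model.variances[c]),
                )
            )
            post.append(lik * model.priors[c])
        assert pred[i] == int(post[1] > post[0])


def test_classify_prior_breaks_likelihood_tie():
    model = DetectorModel(
        feature_names=tuple(FEATURES),
        means=[[0.0] * 4, [0.0] * 4],     # identical classes
        variances=[[1.0] * 4, [1.0] * 4],
        priors=[0.7, 0.3],
    )
    pred = classify_seconds(model, _frame([[0.0] * 4]))
    assert pred[0] == 0  # prior decides; exact ties also go to non-gait


def test_classify_matches_sklearn():
    sklearn = pytest.importorskip("sklearn.naive_bayes")
    X, y = _toy_data(seed=5)
    model = train_detector(X, y)
    ours = classify_seconds(model, X)
    ref = sklearn.GaussianNB().fit(X.to_numpy(), y).predict(X.to_numpy())
    assert (ours == ref).mean() > 0.999


def test_postprocess_rules():
    y = np.r_[np.ones(10), np.zeros(2), np.ones(10)].astype(int)
    out = postprocess_labels(y)
    assert out.sum() == 22  # gap filled into one 22 s run
    y2 = np.r_[np.zeros(5), np.ones(3), np.zeros(5)].astype(int)
    assert postprocess_labels(y2).sum() == 0  # short isolated run deleted
    y3 = np.zeros(20, int)
    assert np.array_equal(postprocess_labels(y3), y3)


@settings(max_examples=100, deadline=None)
@given(st.lists(st.integers(0, 1), min_size=1, max_size=120))
def test_postprocess_properties(labels):
    y = np.array(labels, np.uint8)
    out = postprocess_labels(y)
    # idempotent
    assert np.array_equal(postprocess_labels(out), out)
    # no bout shorter than the minimum
    for _, row in labels_to_bouts(out).iterrows():
        assert row["duration_s"] >= 5
    # new gait seconds only within fill distance of an original gait second
    orig = np.flatnonzero(y == 1)
    for i in np.flatnonzero((out == 1) & (y == 0)):
        assert orig.size and np.min(np.abs(orig - i)) <= 2


def test_labels_to_bouts():
    y = np.r_[np.zeros(3), np.ones(45), np.zeros(2)].astype(int)
    bouts = labels_to_bouts(y)
    assert len(bouts) == 1
    assert bouts.iloc[0].tolist() == [3, 45]
    assert len(labels_to_bouts(np.array([], int))) == 0


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(0, 1), min_size=1, max_size=100))
def test_bout_count_matches_rle_oracle(labels):
    y = np.array(labels, int)
    runs = 0
    prev = 0
    for v in y:
        if v == 1 and prev == 0:
            runs += 1
        prev = v
    assert len(labels_to_bouts(y)) == runs


def test_detection_performance():
    truth = np.r_[np.ones(5), np.zeros(5)].astype(int)
    perf = detection_performance(truth, truth)
    assert perf.iloc[0].tolist() == [100.0, 100.0, 100.0, 100.0]
    allg = detection_performance(np.ones(10, int), truth)
    assert allg.iloc[0]["sensitivity"] == 100.0
    assert allg.iloc[0]["specificity"] == 0.0
    # hand-counted toy: TP=3 FN=1 TN=4 FP=2
    pred = np.array([1, 1, 1, 0, 1, 1, 0, 0, 0, 0])
    tru = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    row = detection_performance(pred, tru).iloc[0]
    assert row["sensitivity"] == pytest.approx(75.0)
    assert row["specificity"] == pytest.approx(100 * 4 / 6)
    assert row["accuracy"] == pytest.approx(70.0)
    assert row["precision"] == pytest.approx(60.0)
    with pytest.raises(ValueError):
        detection_performance(pred[:5], tru)
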