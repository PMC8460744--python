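"""Per-second gait detection: Gaussian Bayes classifier + post-processing.

A diagonal-covariance (naive) Gaussian Bayes classifier on the four
detection features (intensity, periodicity, posture, noisiness) labels
each second gait/non-gait. Two post-classification blocks then smooth the
label stream: short non-gait gaps flanked by gait are filled, and gait
runs shorter than a minimum bout length are deleted, in that order.
Maximal gait runs become bouts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .signal_features import DETECTION_FEATURES

__all__ = [
    "DetectorModel",
    "train_detector",
    "classify_seconds",
    "postprocess_labels",
    "labels_to_bouts",
    "detection_performance",
]

_VAR_FLOOR_RATIO = 1e-9  # relative variance floor, as in standard NB practice


@dataclass
class DetectorModel:
    """Gaussian naive-Bayes parameters: per-class feature means/variances."""

    feature_names: tuple
    means: np.ndarray       # (2, n_features); row 0 = non-gait, row 1 = gait
    variances: np.ndarray   # (2, n_features)
    priors: np.ndarray      # (2,)

    def __post_init__(self):
        self.means = np.asarray(self.means, float)
        self.variances = np.asarray(self.variances, float)
        self.priors = np.asarray(self.priors, float)
        if (self.variances <= 0).any():
            raise ValueError("class variances must be positive")
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
                "priors": self.priors.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DetectorModel":
        d = json.loads(text)
        return cls(
            feature_names=tuple(d["feature_names"]),
            means=np.array(d["means"]),
            variances=np.array(d["variances"]),
            priors=np.array(d["priors"]),
        )


def _feature_matrix(features: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    missing = [c for c in names if c not in features.columns]
    if missing:
        raise ValueError(f"feature schema mismatch, missing columns: {missing}")
    return features[list(names)].to_numpy(float)


def train_detector(
    features: pd.DataFrame,
    labels,
    feature_names: Sequence[str] = DETECTION_FEATURES,
) -> DetectorModel:
    """Estimate per-class Gaussian parameters; priors = class frequencies."""
    y = np.asarray(labels).astype(int)
    X = _feature_matrix(features, feature_names)
    if len(y) != len(X):
        raise ValueError("features and labels length mismatch")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("training labels must contain both classes (0 and 1)")
    means = np.stack([X[y == c].mean(axis=0) for c in (0, 1)])
    variances = np.stack([X[y == c].var(axis=0) for c in (0, 1)])
    for c in (0, 1):
        zero = variances[c] == 0
        if zero.any():
            name = feature_names[int(np.argmax(zero))]
            raise ValueError(f"zero variance in feature {name!r} for class {c}")
    variances = variances + _VAR_FLOOR_RATIO * variances.max()
    priors = np.array([(y == 0).mean(), (y == 1).mean()])
    return DetectorModel(tuple(feature_names), means, variances, priors)


def classify_seconds(model: DetectorModel, features: pd.DataFrame) -> np.ndarray:
    """Per-second labels (1 = gait) by maximum posterior; ties -> non-gait."""
    X = _feature_matrix(features, model.feature_names)
    logpost = np.empty((len(X), 2))
    for c in (0, 1):
        mu, var = model.means[c], model.variances[c]
        ll = -0.5 * (np.log(2 * np.pi * var) + (X - mu) ** 2 / var).sum(axis=1)
        logpost[:, c] = ll + np.log(model.priors[c])
    return (logpost[:, 1] > logpost[:, 0]).astype(np.uint8)


def _runs(labels: np.ndarray):
    """Run-length encoding: yields (value, start, length)."""
    n = len(labels)
    if n == 0:
        return
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    for s, e in zip(starts, ends):
        yield int(labels[s]), int(s), int(e - s)


def postprocess_labels(
    labels,
    fill_gap_max_s: int = 2,
    min_bout_s: int = 5,
) -> np.ndarray:
    """Two smoothing blocks: gap filling then short-run deletion.

    Block 1 relabels non-gait runs of at most ``fill_gap_max_s`` seconds as
    gait when flanked by gait on both sides; block 2 then deletes gait runs
    shorter than ``min_bout_s``. Idempotent on its own output.
    """
    y = np.asarray(labels).astype(np.uint8).copy()
    n = len(y)
    for val, s, ln in list(_runs(y)):
        if val == 0 and ln <= fill_gap_max_s and s > 0 and s + ln < n:
            y[s : s + ln] = 1
    for val, s, ln in list(_runs(y)):
        if val == 1 and ln < min_bout_s:
            y[s : s + ln] = 0
    return y


def labels_to_bouts(labels) -> pd.DataFrame:
    """Maximal gait runs as bouts: columns ``start_s``, ``duration_s``."""
    y = np.asarray(labels).astype(np.uint8)
    rows = [(s, ln) for val, s, ln in _runs(y) if val == 1]
    return pd.DataFrame(rows, columns=["start_s", "duration_s"], dtype=int)


def detection_performance(
    predicted,
    truth,
    subject_ids=None,
) -> pd.DataFrame:
    """Confusion-matrix ratios (%) with gait as the positive class.

    With ``subject_ids`` given, one row per subject plus a ``median`` row;
    otherwise a single pooled row. Columns: sensitivity, specificity,
    accuracy, precision.
    """
    pred = np.asarray(predicted).astype(int)
    tru = np.asarray(truth).astype(int)
    if len(pred) != len(tru):
        raise ValueError("predicted and truth lengths differ")
    if subject_ids is None:
        subject_ids = np.zeros(len(pred), dtype=int)
    sid = np.asarray(subject_ids)

    rows = {}
    for s in pd.unique(sid):
        m = sid == s
        p, t = pred[m], tru[m]
        tp = int(((p == 1) & (t == 1)).sum())
        tn = int(((p == 0) & (t == 0)).sum())
        fp = int(((p == 1) & (t == 0)).sum())
        fn = int(((p == 0) & (t == 1)).sum())
        rows[s] = {
            "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else np.nan,
            "specificity": 100.0 * tn / (tn + fp) if tn + fp else np.nan,
            "accuracy": 100.0 * (tp + tn) / len(p),
            "precision": 100.0 * tp / (tp + fp) if tp + fp else np.nan,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.loc["median"] = out.median()
    return out
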