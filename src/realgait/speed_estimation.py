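"""Instantaneous (per-second) gait-speed estimation by linear regression.

A single non-personalized model — ordinary least squares of true speed on
the per-second speed features (energy, step frequency, mean acceleration,
wrist-swing intensity) — is fit once on pooled training subjects and then
applied per gait second. Predictions are clipped to a physiological range;
seconds whose cadence could not be measured inherit the bout's running
median speed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .signal_features import SPEED_FEATURES

__all__ = ["SpeedModel", "fit_speed_model", "estimate_speed", "speed_rmse", "SPEED_CLIP"]

SPEED_CLIP = (0.1, 4.0)  # m/s


@dataclass
class SpeedModel:
    feature_names: tuple
    intercept: float
    coef: np.ndarray

    def __post_init__(self):
        self.coef = np.asarray(self.coef, float)
        if not np.isfinite(self.coef).all() or not np.isfinite(self.intercept):
            raise ValueError("model coefficients must be finite")

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = features[list(self.feature_names)].to_numpy(float)
        return self.intercept + X @ self.coef

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "intercept": self.intercept,
                "coef": self.coef.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SpeedModel":
        d = json.loads(text)
        return cls(tuple(d["feature_names"]), float(d["intercept"]), np.array(d["coef"]))


def fit_speed_model(
    features: pd.DataFrame,
    true_speed,
    feature_names: Sequence[str] = SPEED_FEATURES,
) -> SpeedModel:
    """OLS fit of per-second speed on gait-second features.

    Rows must be gait seconds with a defined step frequency (no NaNs).
    Requires at least twice as many rows as coefficients; a rank-deficient
    design raises.
    """
    y = np.asarray(true_speed, float)
    X = features[list(feature_names)].to_numpy(float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("training rows must have defined features and speeds")
    k = X.shape[1] + 1
    if len(y) < 2 * k:
        raise ValueError(f"need at least {2 * k} rows to fit {k} coefficients")
    A = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(A) < k:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return SpeedModel(tuple(feature_names), float(beta[0]), beta[1:])


def estimate_speed(
    model: SpeedModel,
    features: pd.DataFrame,
    bouts: pd.DataFrame,
) -> pd.Series:
    """Per-second speed for every second inside a bout, clipped to [0.1, 4] m/s.

    Seconds with an undefined step frequency inherit the running median of
    the bout's defined estimates (the bout median; if a bout has none, the
    series median; 1.2 m/s as a last resort). Indexed by second.
    """
    n_sec = len(features)
    est_rows = []
    for _, b in bouts.iterrows():
        s0, d = int(b["start_s"]), int(b["duration_s"])
        if s0 < 0 or s0 + d > n_sec:
            raise ValueError("bout references seconds outside the feature series")
        idx = np.arange(s0, s0 + d)
        sub = features.iloc[idx]
        defined = sub[list(model.feature_names)].notna().all(axis=1).to_numpy()
        pred = np.full(d, np.nan)
        if defined.any():
            pred[defined] = np.clip(model.predict(sub[defined]), *SPEED_CLIP)
        if (~defined).any():
            fill = (
                float(np.median(pred[defined])) if defined.any() else np.nan
            )
            pred[~defined] = fill
        est_rows.append(pd.Series(pred, index=idx))
    if not est_rows:
        return pd.Series(dtype=float, name="speed_mps")
    out = pd.concat(est_rows)
    global_med = float(out.dropna().median()) if out.notna().any() else 1.2
    out = out.fillna(global_med)
    out.name = "speed_mps"
    return out


def speed_rmse(
    estimated: pd.Series,
    truth,
    subject_ids=None,
) -> pd.DataFrame:
    """Per-subject RMSE over matched gait seconds, plus the cohort median.

    ``truth`` is a per-second array aligned with the estimate's index (or a
    Series sharing that index). NaN truth seconds are ignored.
    """
    if not isinstance(truth, pd.Series):
        truth = pd.Series(np.asarray(truth, float))
    common = estimated.index.intersection(truth.index)
    t = truth.loc[common]
    e = estimated.loc[common]
    keep = (t.notna() & e.notna()).to_numpy()
    if not keep.any():
        raise ValueError("no overlapping gait seconds between estimate and truth")
    err = (e.to_numpy() - t.to_numpy())[keep]
    if subject_ids is None:
        sid = np.zeros(int(keep.sum()), dtype=int)
    else:
        if not isinstance(subject_ids, pd.Series):
            raise TypeError("subject_ids must be a Series aligned on seconds")
        sid = subject_ids.loc[common].to_numpy()[keep]
    rows = {
        s: {"rmse": float(np.sqrt(np.mean(err[sid == s] ** 2)))}
        for s in pd.unique(sid)
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.loc["median"] = out.median()
    return out
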