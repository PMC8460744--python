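"""Operationalization of the clinical covariates used in the association layer.

Frailty is proxied by the Fried phenotype reduced to muscle weakness:
sex-specific handgrip-strength cutoffs stratified by BMI. The remaining
covariates (BMI class, decadal age group, weekly moderate-to-vigorous
physical activity) follow the conventional epidemiological categorizations.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "classify_frailty",
    "bmi_category",
    "age_group",
    "pa_category",
    "best_grip",
    "add_covariates",
    "FRAILTY_CUTOFFS",
]

#: Sex-specific grip-strength cutoffs (kg) per BMI stratum.  A subject is
#: frail when grip <= cutoff in the stratum where bmi <= upper bound
#: (strata are lower-exclusive, upper-inclusive).
FRAILTY_CUTOFFS = {
    "man": [(24.0, 29.0), (28.0, 30.0), (np.inf, 32.0)],
    "woman": [(23.0, 17.0), (26.0, 17.3), (29.0, 18.0), (np.inf, 21.0)],
}

AGE_GROUPS = ["45-54", "55-64", "65-74", "75+"]
BMI_CATEGORIES = ["normal", "overweight", "obese"]
PA_LEVELS = ["inactive", "active"]


def classify_frailty(sex: str, bmi: float, grip_kg: float) -> bool:
    """Return True (frail) per the weakness-based Fried phenotype proxy.

    Parameters
    ----------
    sex : {"man", "woman"}
    bmi : body mass index in kg/m^2, must be positive.
    grip_kg : best handgrip strength in kg, non-negative.
    """
    if sex not in FRAILTY_CUTOFFS:
        raise ValueError(f"sex must be 'man' or 'woman', got {sex!r}")
    if not bmi > 0:
        raise ValueError(f"bmi must be positive, got {bmi}")
    if grip_kg < 0:
        raise ValueError(f"grip_kg must be non-negative, got {grip_kg}")
    for bmi_upper, cutoff in FRAILTY_CUTOFFS[sex]:
        if bmi <= bmi_upper:
            return grip_kg <= cutoff
    raise AssertionError("unreachable: last stratum is unbounded")


def bmi_category(bmi: float) -> str:
    """Categorize BMI: <25 normal (underweight merged), [25, 30) overweight, >=30 obese."""
    if not bmi > 0:
        raise ValueError(f"bmi must be positive, got {bmi}")
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def age_group(age: float) -> str:
    """Decadal age group: 45-54, 55-64, 65-74, 75+. Ages below 45 are out of range."""
    if age < 45:
        raise ValueError(f"age below cohort range (45): {age}")
    if age < 55:
        return "45-54"
    if age < 65:
        return "55-64"
    if age < 75:
        return "65-74"
    return "75+"


def pa_category(weekly_mvpa: float) -> str:
    """Physical-activity level: active iff >= 150 min/week of MVPA."""
    if weekly_mvpa < 0:
        raise ValueError(f"weekly_mvpa must be non-negative, got {weekly_mvpa}")
    return "active" if weekly_mvpa >= 150.0 else "inactive"


def best_grip(measurements: Sequence[float]) -> float:
    """Best of up to three consecutive dynamometer readings (kg).

    Returns NaN for an empty sequence (missing measurement).
    """
    vals = [float(v) for v in measurements]
    if len(vals) > 3:
        raise ValueError("at most three grip measurements expected")
    if any(v < 0 for v in vals):
        raise ValueError("grip measurements must be non-negative")
    if not vals:
        return float("nan")
    return max(vals)


def _frailty_vector(sex: np.ndarray, bmi: np.ndarray, grip: np.ndarray) -> np.ndarray:
    frail = np.zeros(len(sex), dtype=bool)
    for s, strata in FRAILTY_CUTOFFS.items():
        mask_sex = sex == s
        lower = -np.inf
        for bmi_upper, cutoff in strata:
            in_stratum = mask_sex & (bmi > lower) & (bmi <= bmi_upper)
            frail[in_stratum] = grip[in_stratum] <= cutoff
            lower = bmi_upper
    return frail


def add_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Append categorical covariates and the frailty flag to a cohort table.

    Requires columns ``sex``, ``age``, ``bmi``, ``weekly_mvpa``, ``grip_kg``;
    adds ``age_group``, ``bmi_category``, ``pa_level`` (ordered categoricals,
    first level = reference) and boolean ``frail``.
    """
    out = table.copy()
    age = out["age"].to_numpy(float)
    if (age < 45).any():
        raise ValueError("ages below 45 are outside the cohort range")
    bmi = out["bmi"].to_numpy(float)
    if (bmi <= 0).any():
        raise ValueError("non-positive BMI")
    out["age_group"] = pd.Categorical(
        np.select([age < 55, age < 65, age < 75], AGE_GROUPS[:3], default="75+"),
        categories=AGE_GROUPS,
        ordered=True,
    )
    out["bmi_category"] = pd.Categorical(
        np.select([bmi < 25.0, bmi < 30.0], BMI_CATEGORIES[:2], default="obese"),
        categories=BMI_CATEGORIES,
        ordered=True,
    )
    out["pa_level"] = pd.Categorical(
        np.where(out["weekly_mvpa"].to_numpy(float) >= 150.0, "active", "inactive"),
        categories=PA_LEVELS,
        ordered=True,
    )
    out["frail"] = _frailty_vector(
        out["sex"].to_numpy(object), bmi, out["grip_kg"].to_numpy(float)
    )
    return out
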