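"""Bout-duration stratification and per-subject speed-distribution metrics.

Detected gait bouts are stratified by duration — SHORT (< 30 s),
MEDIUM (30–120 s, inclusive), LONG (> 120 s) — and, within each category
plus the pooled ALL category, a subject's per-second speeds are summarized
by eight distribution metrics: mode (kernel-density peak, the preferred
speed), median, mean, 75th/90th/95th percentiles, SD, and maximum.

Pooling is duration-weighted: the sample unit is the gait second, so a
120 s bout contributes 120 speed samples. A per-bout-mean pooling mode is
available for sensitivity checks.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BoutCategory",
    "METRIC_NAMES",
    "categorize_bouts",
    "filter_valid_days",
    "compute_preferred_speed",
    "compute_metrics",
    "bout_share",
    "subject_metric_rows",
]

SHORT_MAX_S = 30.0   # exclusive upper edge of SHORT
MEDIUM_MAX_S = 120.0  # inclusive upper edge of MEDIUM
DAY_LENGTH_S = 86_400
MIN_SAMPLES = 10      # below this a category's metric row is missing

METRIC_NAMES = ["mode", "median", "mean", "p75", "p90", "p95", "sd", "max"]

KDE_GRID = np.round(np.arange(0.0, 4.0 + 1e-9, 0.01), 2)


class BoutCategory(str, Enum):
    SHORT = "short"
    MEDIUM = "medium"
    LONG = "long"
    ALL = "all"


def categorize_bouts(durations_s) -> np.ndarray:
    """Assign each bout duration to SHORT/MEDIUM/LONG.

    Boundaries: 30 s and 120 s both fall in MEDIUM.
    """
    d = np.asarray(durations_s, dtype=float)
    if (d <= 0).any():
        raise ValueError("bout durations must be positive")
    out = np.where(
        d < SHORT_MAX_S,
        BoutCategory.SHORT.value,
        np.where(d <= MEDIUM_MAX_S, BoutCategory.MEDIUM.value, BoutCategory.LONG.value),
    )
    return out


def filter_valid_days(bouts: pd.DataFrame, n_days: int, day_length_s: int = DAY_LENGTH_S) -> dict:
    """Count valid days (calendar days with >= 1 bout start) for one subject.

    ``bouts`` needs a ``start_s`` column of seconds from recording start.
    Returns ``{"n_valid_days": int, "included": bool}``; a subject with
    zero valid days is flagged for exclusion (no walking-speed data).
    """
    if len(bouts) == 0:
        return {"n_valid_days": 0, "included": False}
    start = bouts["start_s"].to_numpy(float)
    if (start < 0).any() or (start >= n_days * day_length_s).any():
        raise ValueError("bout start outside the monitoring window")
    days = np.unique((start // day_length_s).astype(int))
    return {"n_valid_days": int(len(days)), "included": True}


def _silverman_bandwidth(x: np.ndarray) -> float:
    # matches gaussian_kde(bw_method="silverman") in one dimension
    return float(np.std(x, ddof=1) * (0.75 * len(x)) ** (-0.2))


def kde_density(speeds, grid: np.ndarray = KDE_GRID) -> np.ndarray:
    """Gaussian KDE (Silverman bandwidth) evaluated on the fixed speed grid.

    Computed by linear binning onto the grid followed by convolution with
    the Gaussian kernel — equivalent to the direct kernel sum on this grid
    (the bandwidth is always several grid steps wide) but O(n + grid).
    """
    x = np.asarray(speeds, dtype=float)
    h = _silverman_bandwidth(x)
    step = grid[1] - grid[0]
    lo = grid[0]
    # linear binning: split each sample's weight between flanking grid points
    pos = np.clip((x - lo) / step, 0, len(grid) - 1)
    left = np.floor(pos).astype(int)
    frac = pos - left
    right = np.minimum(left + 1, len(grid) - 1)
    counts = np.bincount(left, weights=1.0 - frac, minlength=len(grid))
    counts += np.bincount(right, weights=frac, minlength=len(grid))
    half = int(np.ceil(6 * h / step))
    u = np.arange(-half, half + 1) * step
    kernel = np.exp(-0.5 * (u / h) ** 2) / (h * np.sqrt(2 * np.pi))
    dens = np.convolve(counts, kernel, mode="full")[half : half + len(grid)]
    return dens / len(x)


def compute_preferred_speed(speeds, min_samples: int = MIN_SAMPLES) -> float:
    """Preferred (usual) speed: mode of the Gaussian-KDE density of speeds.

    Silverman-bandwidth KDE evaluated on the fixed grid 0–4 m/s in 0.01
    steps; returns the grid argmax (ties break toward the lowest speed).
    NaN when fewer than ``min_samples`` samples are available.
    """
    x = np.asarray(speeds, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_samples:
        return float("nan")
    if np.ptp(x) == 0.0:  # degenerate sample: density peaks at the point mass
        return float(x[0])
    dens = kde_density(x)
    return float(KDE_GRID[int(np.argmax(dens))])


def compute_metrics(speeds, min_samples: int = MIN_SAMPLES) -> dict:
    """Distribution metrics of a pooled per-second speed sample (m/s).

    Percentiles use linear interpolation between order statistics; SD is
    the sample SD (ddof=1); mode is the KDE preferred speed. Samples with
    fewer than ``min_samples`` entries yield an all-NaN (missing) row.
    """
    x = np.asarray(speeds, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    row = {name: float("nan") for name in METRIC_NAMES}
    row["n_seconds"] = n
    if n < min_samples:
        return row
    p75, p90, p95 = np.percentile(x, [75, 90, 95])
    row.update(
        mode=compute_preferred_speed(x, min_samples=min_samples),
        median=float(np.median(x)),
        mean=float(np.mean(x)),
        p75=float(p75),
        p90=float(p90),
        p95=float(p95),
        sd=float(np.std(x, ddof=1)),
        max=float(np.max(x)),
    )
    return row


def bout_share(durations_s) -> dict:
    """Percentage of a subject's bouts in each duration category (sums to 100)."""
    d = np.asarray(durations_s, dtype=float)
    if len(d) == 0:
        raise ValueError("bout_share requires at least one bout")
    cats = categorize_bouts(d)
    n = len(cats)
    return {
        c.value: 100.0 * float(np.sum(cats == c.value)) / n
        for c in (BoutCategory.SHORT, BoutCategory.MEDIUM, BoutCategory.LONG)
    }


def subject_metric_rows(
    durations_s,
    bout_speeds: Iterable[np.ndarray],
    per_bout_mean: bool = False,
) -> dict:
    """Metric rows for one subject, keyed by category (short/medium/long/all).

    ``bout_speeds`` holds one per-second speed array per bout, aligned with
    ``durations_s``. With ``per_bout_mean=True`` each bout contributes its
    mean speed once instead of one sample per second (sensitivity mode).
    """
    d = np.asarray(durations_s, dtype=float)
    cats = categorize_bouts(d) if len(d) else np.array([], dtype=object)
    samples = {c.value: [] for c in BoutCategory}
    for cat, sp in zip(cats, bout_speeds):
        arr = np.asarray(sp, dtype=float)
        if per_bout_mean:
            arr = np.array([np.mean(arr)]) if len(arr) else arr
        samples[cat].append(arr)
        samples[BoutCategory.ALL.value].append(arr)
    out = {}
    for cat in BoutCategory:
        pooled = (
            np.concatenate(samples[cat.value]) if samples[cat.value] else np.array([])
        )
        row = compute_metrics(pooled)
        row["n_bouts"] = int(np.sum(cats == cat.value)) if cat != BoutCategory.ALL else len(d)
        out[cat.value] = row
    return out
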