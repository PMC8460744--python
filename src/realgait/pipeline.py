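"""End-to-end orchestration: simulate → detect → speed → metrics → analyze.

Two entry points cover the two fidelities:

* :func:`metric_cohort_pipeline` — schedules and per-second speeds only
  (no raw signal), scaling to cohorts of thousands of subjects; feeds the
  association layer.
* :func:`signal_benchmark` — raw-signal synthesis, detector training and
  per-second speed regression with a subject-level train/test split;
  reports the detector operating point and speed RMSE on held-out
  subjects.

A single run seed is expanded into independent per-stage/per-subject
streams so results are reproducible bit-for-bit from a saved config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import association_analysis as assoc
from . import bout_detection as det
from . import signal_features as feat
from . import speed_estimation as spd
from . import speed_metrics as met
from .clinical_scores import add_covariates
from .io import save_recording, write_manifest
from .synthetic_data import (
    CohortConfig,
    ScheduleConfig,
    SignalConfig,
    cohort_to_frame,
    generate_cohort,
    generate_schedule,
    synthesize_signal,
)

__all__ = [
    "RunConfig",
    "metric_cohort_pipeline",
    "signal_benchmark",
    "run_pipeline",
    "subject_seeds",
]

MAX_SEED = 2**31 - 1


def subject_seeds(seed: int, n: int, stream: str) -> np.ndarray:
    """Independent integer seeds for a named stage, derived from the run seed."""
    import zlib

    root = np.random.SeedSequence([seed, zlib.crc32(stream.encode()) % MAX_SEED])
    rng = np.random.default_rng(root)
    return rng.integers(0, MAX_SEED, size=n)


# ---------------------------------------------------------------------------
# metric-level cohort
# ---------------------------------------------------------------------------

def metric_cohort_pipeline(
    n: int,
    n_days: int,
    seed: int,
    cohort_config: Optional[CohortConfig] = None,
    schedule_config: Optional[ScheduleConfig] = None,
    per_bout_mean: bool = False,
) -> pd.DataFrame:
    """Cohort table: covariates, frailty flag, and the full speed-metric set.

    For each subject a 13-day (by default) activity schedule is simulated
    and the ground-truth per-second speeds are pooled by bout-duration
    category into the eight distribution metrics (columns
    ``<metric>_<category>``), plus bout shares, valid-day counts and an
    inclusion flag.
    """
    profiles = generate_cohort(n, seed, cohort_config)
    table = add_covariates(cohort_to_frame(profiles))
    sched_cfg = schedule_config or ScheduleConfig()
    seeds = subject_seeds(seed, n, "schedule")
    rows = []
    for prof, s in zip(profiles, seeds):
        schedule = generate_schedule(prof, n_days, int(s), sched_cfg)
        bouts = schedule.gait_bouts()
        traces = schedule.gait_speed_traces()
        row = {}
        metric_rows = met.subject_metric_rows(
            bouts["duration_s"].to_numpy(), traces, per_bout_mean=per_bout_mean
        )
        for cat, mr in metric_rows.items():
            for name in met.METRIC_NAMES:
                row[f"{name}_{cat}"] = mr[name]
            row[f"n_seconds_{cat}"] = mr["n_seconds"]
            row[f"n_bouts_{cat}"] = mr["n_bouts"]
        if len(bouts):
            for cat, share in met.bout_share(bouts["duration_s"].to_numpy()).items():
                row[f"share_{cat}"] = share
        vd = met.filter_valid_days(bouts, n_days, sched_cfg.day_length_s)
        row["n_valid_days"] = vd["n_valid_days"]
        row["included"] = vd["included"]
        rows.append(row)
    out = pd.concat([table, pd.DataFrame(rows, index=table.index)], axis=1)
    return out[out["included"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# signal-level benchmark
# ---------------------------------------------------------------------------

def _subject_stage(profile, sched_cfg, sig_cfg, sched_seed, sig_seed):
    schedule = generate_schedule(profile, 1, int(sched_seed), sched_cfg)
    rec = synthesize_signal(schedule, int(sig_seed), sig_cfg)
    enhanced = feat.enhance_signal(rec)
    features = feat.extract_features(enhanced, rec)
    return rec, features


def signal_benchmark(
    n_subjects: int = 40,
    hours: float = 4.0,
    seed: int = 0,
    train_frac: float = 0.5,
    schedule_config: Optional[ScheduleConfig] = None,
    signal_config: Optional[SignalConfig] = None,
    fill_gap_max_s: int = 2,
    min_bout_s: int = 5,
) -> dict:
    """Detector + speed-estimator benchmark on held-out synthetic subjects.

    Subjects are synthesized at signal level (default 40 × 4 h), split by
    subject into train/test halves; the Bayes detector and the pooled
    (non-personalized) speed regression are fit on the training half. On
    each test subject, per-second detection performance is scored after
    post-processing, and speed RMSE is computed over the true gait
    seconds. Returns per-subject tables and cohort medians.
    """
    sched_cfg = schedule_config or ScheduleConfig.signal_benchmark(hours)
    sig_cfg = signal_config or SignalConfig()
    profiles = generate_cohort(n_subjects, seed)
    n_train = int(round(train_frac * n_subjects))
    sched_seeds = subject_seeds(seed, n_subjects, "bench-schedule")
    sig_seeds = subject_seeds(seed, n_subjects, "bench-signal")

    train_feats, train_labels = [], []
    train_speed_feats, train_speeds = [], []
    test_cache = []
    for i, prof in enumerate(profiles):
        rec, features = _subject_stage(
            prof, sched_cfg, sig_cfg, sched_seeds[i], sig_seeds[i]
        )
        if i < n_train:
            train_feats.append(features)
            train_labels.append(rec.truth_label)
            gait = rec.truth_label == 1
            ok = gait & features["step_freq"].notna().to_numpy()
            train_speed_feats.append(features[ok])
            train_speeds.append(rec.truth_speed[ok])
        else:
            test_cache.append((prof.subject_id, rec, features))

    model = det.train_detector(pd.concat(train_feats), np.concatenate(train_labels))
    speed_model = spd.fit_speed_model(
        pd.concat(train_speed_feats), np.concatenate(train_speeds)
    )

    perf_rows, rmse_rows = {}, {}
    for sid, rec, features in test_cache:
        pred = det.postprocess_labels(
            det.classify_seconds(model, features), fill_gap_max_s, min_bout_s
        )
        perf = det.detection_performance(pred, rec.truth_label)
        perf_rows[sid] = perf.iloc[0].to_dict()
        true_bouts = det.labels_to_bouts(rec.truth_label)
        est = spd.estimate_speed(speed_model, features, true_bouts)
        rmse = spd.speed_rmse(est, pd.Series(rec.truth_speed))
        rmse_rows[sid] = {"rmse": float(rmse.loc[rmse.index[0], "rmse"])}

    perf_df = pd.DataFrame.from_dict(perf_rows, orient="index")
    rmse_df = pd.DataFrame.from_dict(rmse_rows, orient="index")
    return {
        "detector_model": model,
        "speed_model": speed_model,
        "performance": perf_df,
        "rmse": rmse_df,
        "medians": {
            "sensitivity": float(perf_df["sensitivity"].median()),
            "specificity": float(perf_df["specificity"].median()),
            "accuracy": float(perf_df["accuracy"].median()),
            "precision": float(perf_df["precision"].median()),
            "rmse": float(rmse_df["rmse"].median()),
        },
    }


# ---------------------------------------------------------------------------
# full pipeline with persisted artifacts
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable settings for a reproducible end-to-end run."""

    seed: int = 0
    fidelity: str = "metric"        # "metric" | "signal"
    n_subjects: int = 200
    n_days: int = 13
    hours_per_day: float = 4.0      # signal fidelity only
    per_bout_mean: bool = False
    runner_speed_threshold: float = 2.5
    fill_gap_max_s: int = 2
    min_bout_s: int = 5

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        if self.fidelity not in ("metric", "signal"):
            raise ValueError("fidelity must be 'metric' or 'signal'")
        if self.n_subjects < 1 or self.n_days < 1:
            raise ValueError("n_subjects and n_days must be positive")


def run_pipeline(config: RunConfig, out_dir: Path) -> dict:
    """Execute the configured pipeline, persisting every stage's outputs.

    Metric fidelity emits the cohort table, the speed-metric table, the
    frailty/grip nested-model reports and both sensitivity analyses;
    signal fidelity emits the trained detector and speed models plus the
    held-out benchmark report. A sha256 manifest covers all artifacts.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = []
    config.to_yaml(out_dir / "config.yaml")
    artifacts.append(out_dir / "config.yaml")
    results = {}

    if config.fidelity == "metric":
        table = metric_cohort_pipeline(
            config.n_subjects,
            config.n_days,
            config.seed,
            per_bout_mean=config.per_bout_mean,
        )
        cohort_path = out_dir / "cohort_metrics.csv"
        table.to_csv(cohort_path, index=False)
        artifacts.append(cohort_path)

        frailty = assoc.run_frailty_analysis(table)
        grip = assoc.run_grip_analysis(table)
        for name, report in [("frailty_report", frailty), ("grip_report", grip)]:
            p = out_dir / f"{name}.csv"
            report.to_csv(p, index=False)
            artifacts.append(p)

        filtered, n_excl = assoc.sensitivity_exclude_runners(
            table, config.runner_speed_threshold
        )
        age65 = assoc.sensitivity_age65(table)
        sens = {
            "runners_excluded": n_excl,
            "n_after_runner_exclusion": len(filtered),
            "n_age65": len(age65),
        }
        for name, sub in [("norunners", filtered), ("age65", age65)]:
            rep = assoc.run_frailty_analysis(sub)
            p = out_dir / f"frailty_report_{name}.csv"
            rep.to_csv(p, index=False)
            artifacts.append(p)
        spath = out_dir / "sensitivity.json"
        spath.write_text(json.dumps(sens, indent=1))
        artifacts.append(spath)
        results = {"table": table, "frailty": frailty, "grip": grip, **sens}
    else:
        bench = signal_benchmark(
            n_subjects=config.n_subjects,
            hours=config.hours_per_day,
            seed=config.seed,
            fill_gap_max_s=config.fill_gap_max_s,
            min_bout_s=config.min_bout_s,
        )
        (out_dir / "detector_model.json").write_text(bench["detector_model"].to_json())
        (out_dir / "speed_model.json").write_text(bench["speed_model"].to_json())
        bench["performance"].to_csv(out_dir / "detection_performance.csv")
        bench["rmse"].to_csv(out_dir / "speed_rmse.csv")
        report = out_dir / "benchmark_report.json"
        report.write_text(json.dumps(bench["medians"], indent=1))
        artifacts += [
            out_dir / "detector_model.json",
            out_dir / "speed_model.json",
            out_dir / "detection_performance.csv",
            out_dir / "speed_rmse.csv",
            report,
        ]
        results = bench
    write_manifest(out_dir, artifacts)
    return results
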