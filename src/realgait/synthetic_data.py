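"""Synthetic free-living cohort, activity-schedule and wrist-signal generator.

Downstream stages (detection, speed regression, metrics, association) are
exercised on simulated data at two fidelities:

* **metric level** — per-second gait speeds emitted directly from activity
  schedules, cheap enough for cohorts of ~2000 subjects over 13 days;
* **signal level** — raw 50 Hz tri-axial wrist acceleration (±8 g) with
  per-second ground-truth labels and speeds, for small-n detector and
  speed-estimator benchmarks.

The generator emulates a community-dwelling adult cohort: ~54% women, ages
45+, BMI/physical-activity marginals typical of such samples, preferred
walking speeds around 1–1.6 m/s declining with age and BMI, grip strength
declining with age and coupled to walking speed so that the weakness-based
frailty rule yields a prevalence near 9%. Daily activity follows a
repetitive pattern — an inactive night, morning and afternoon active
periods, occasional evening bouts — with bout durations drawn from a
65/30/5 short/medium/long mixture and a larger speed dispersion for long
bouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "SubjectProfile",
    "ScheduleEvent",
    "ActivitySchedule",
    "SignalRecording",
    "CohortConfig",
    "ScheduleConfig",
    "SignalConfig",
    "generate_cohort",
    "cohort_to_frame",
    "generate_schedule",
    "synthesize_signal",
    "simulate_association_cohort",
]

GAIT = "gait"
NONGAIT_ACTIVE = "nongait_active"
REST = "rest"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject covariates and latent gait parameters."""

    subject_id: str
    sex: str                      # {"man", "woman"}
    age: float                    # years
    bmi: float                    # kg/m^2
    weekly_mvpa: float            # minutes/week of moderate-to-vigorous PA
    grip_kg: float                # best handgrip strength, kg
    preferred_speed_true: float   # latent usual walking speed, m/s
    within_subject_speed_sd: float  # between-bout speed SD, m/s

    def __post_init__(self):
        if not (45 <= self.age <= 95):
            raise ValueError(f"age out of range [45, 95]: {self.age}")
        if not (15 <= self.bmi <= 50):
            raise ValueError(f"bmi out of range [15, 50]: {self.bmi}")
        if self.grip_kg < 0:
            raise ValueError("grip_kg must be non-negative")
        if not (0.4 < self.preferred_speed_true < 2.2):
            raise ValueError("preferred_speed_true outside (0.4, 2.2) m/s")
        if self.weekly_mvpa < 0:
            raise ValueError("weekly_mvpa must be non-negative")


@dataclass(frozen=True)
class ScheduleEvent:
    start_s: int
    duration_s: int
    kind: str                     # gait | nongait_active | rest
    speed_trace: Optional[np.ndarray] = None  # per-second m/s, gait only

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("event duration must be positive")
        if self.kind == GAIT:
            if self.speed_trace is None or len(self.speed_trace) != self.duration_s:
                raise ValueError("gait event needs one speed per second")
            if (np.asarray(self.speed_trace) <= 0).any():
                raise ValueError("gait speeds must be positive")


@dataclass
class ActivitySchedule:
    subject_id: str
    n_days: int
    day_length_s: int
    events: List[ScheduleEvent]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        prev_end = -1
        for ev in self.events:
            if ev.start_s <= prev_end:
                raise ValueError("events overlap or are unsorted")
            prev_end = ev.start_s + ev.duration_s - 1
        if self.events and prev_end >= self.n_days * self.day_length_s:
            raise ValueError("event extends past the recording window")

    @property
    def total_seconds(self) -> int:
        return self.n_days * self.day_length_s

    def gait_bouts(self) -> pd.DataFrame:
        rows = [
            (ev.start_s, ev.duration_s)
            for ev in self.events
            if ev.kind == GAIT
        ]
        return pd.DataFrame(rows, columns=["start_s", "duration_s"], dtype=int)

    def gait_speed_traces(self) -> List[np.ndarray]:
        return [np.asarray(ev.speed_trace) for ev in self.events if ev.kind == GAIT]

    def truth_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        """Per-second (label, speed): label 1 = gait; speed NaN off-gait."""
        n = self.total_seconds
        label = np.zeros(n, dtype=np.uint8)
        speed = np.full(n, np.nan)
        for ev in self.events:
            if ev.kind == GAIT:
                sl = slice(ev.start_s, ev.start_s + ev.duration_s)
                label[sl] = 1
                speed[sl] = ev.speed_trace
        return label, speed


@dataclass
class SignalRecording:
    """Raw tri-axial wrist acceleration with ground-truth channels."""

    sampling_rate: int
    acceleration: np.ndarray      # (n_samples, 3) in g, clipped to ±8
    truth_label: np.ndarray       # per-second, 1 = gait
    truth_speed: np.ndarray       # per-second m/s, NaN off gait

    def __post_init__(self):
        n_sec = self.acceleration.shape[0] // self.sampling_rate
        if len(self.truth_label) != n_sec or len(self.truth_speed) != n_sec:
            raise ValueError("truth channels must have one entry per full second")
        if np.abs(self.acceleration).max(initial=0.0) > 8.0 + 1e-9:
            raise ValueError("acceleration exceeds the ±8 g device range")

    @property
    def n_seconds(self) -> int:
        return len(self.truth_label)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Covariate marginals and linear effect sizes for cohort generation."""

    p_woman: float = 0.537
    age_group_probs: Tuple[float, ...] = (0.296, 0.324, 0.259, 0.121)
    age_group_bounds: Tuple[Tuple[float, float], ...] = (
        (45.0, 55.0), (55.0, 65.0), (65.0, 75.0), (75.0, 86.0),
    )
    bmi_category_probs: Tuple[float, ...] = (0.412, 0.406, 0.182)
    p_active: float = 0.388
    # preferred walking speed (m/s): linear model on covariates
    speed_base: float = 1.38
    speed_b_man: float = 0.08
    speed_b_age: float = -0.009    # per year, centered at 62
    speed_b_bmi: float = -0.012    # per kg/m^2, centered at 26
    speed_b_active: float = 0.10
    speed_noise_sd: float = 0.10
    speed_clip: Tuple[float, float] = (0.5, 2.1)
    # between-bout speed SD per subject
    within_sd_range: Tuple[float, float] = (0.06, 0.14)
    # grip strength (kg): linear model; intercepts/noise set the frail share
    grip_base_man: float = 43.0
    grip_base_woman: float = 26.0
    grip_b_age: float = -0.25      # per year, centered at 62
    grip_b_speed: float = 6.0      # per m/s, centered at 1.3
    grip_sd_man: float = 8.5
    grip_sd_woman: float = 5.5
    frail_prevalence_target: float = 0.092  # informational target

    def validate(self) -> None:
        if not (0 <= self.p_woman <= 1 and 0 <= self.p_active <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        for probs in (self.age_group_probs, self.bmi_category_probs):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError("category probabilities must be a distribution")
        if self.speed_noise_sd < 0 or self.grip_sd_man < 0 or self.grip_sd_woman < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass(frozen=True)
class ScheduleConfig:
    """Daily activity-pattern settings.

    ``active_windows`` are (start, end, weight) fractions of the day; bouts
    and other active events are placed inside them, leaving the remainder
    (the night block and inter-window stretches) at rest.
    """

    day_length_s: int = 86_400
    active_windows: Tuple[Tuple[float, float, float], ...] = (
        (0.35, 0.50, 0.45),   # morning
        (0.55, 0.75, 0.45),   # afternoon
        (0.79, 0.87, 0.10),   # occasional evening bouts
    )
    bouts_per_day_mean: float = 25.0
    nongait_per_day_mean: float = 15.0
    category_probs: Tuple[float, float, float] = (0.65, 0.30, 0.05)
    short_range_s: Tuple[int, int] = (5, 29)
    medium_range_s: Tuple[int, int] = (30, 120)
    long_excess_mean_s: float = 80.0   # LONG = 121 + Exp(mean), capped
    long_max_s: int = 600
    long_sd_multiplier: float = 1.8    # speed dispersion boost for long bouts
    per_second_jitter_frac: float = 0.4  # second-to-second SD as a fraction
                                         # of the subject's between-bout SD
    jitter_rho: float = 0.7
    nongait_duration_range_s: Tuple[int, int] = (20, 180)
    min_gap_s: int = 10
    bout_speed_clip: Tuple[float, float] = (0.4, 2.4)

    @classmethod
    def signal_benchmark(cls, hours: float = 4.0) -> "ScheduleConfig":
        """Compressed single-day template for signal-level benchmarks."""
        return cls(
            day_length_s=int(hours * 3600),
            active_windows=((0.02, 0.48, 0.5), (0.52, 0.98, 0.5)),
            bouts_per_day_mean=60.0,
            nongait_per_day_mean=40.0,
            nongait_duration_range_s=(20, 120),
        )


@dataclass(frozen=True)
class SignalConfig:
    """Wrist-kinematics signal model.

    During gait the device sees, along the (slowly wobbling) gravity axis, a
    step-impact harmonic at the step frequency plus an arm-swing component
    at half the step frequency; the step frequency is an affine function of
    speed, ``step_freq = 1.45 + 0.35 * speed`` Hz by default. Non-gait
    active periods contain aperiodic band-limited movement; rest is gravity
    plus sensor noise.
    """

    sampling_rate: int = 50
    noise_sd: float = 0.03                 # white sensor noise per axis, g
    step_freq_base: float = 1.45           # Hz
    step_freq_slope: float = 0.35          # Hz per m/s
    impact_amp_base: float = 0.30          # g, at speed 0
    impact_amp_slope: float = 0.18         # g per m/s
    swing_ratio: float = 0.5               # swing amplitude / impact amplitude
    posture_deg: Tuple[float, float, float] = (75.0, 40.0, 10.0)  # gait/active/rest
    posture_sd_deg: float = 8.0
    nongait_band_hz: Tuple[float, float] = (0.3, 3.0)
    nongait_rms: float = 0.15              # g, per axis before gravity
    wobble_amp_deg: float = 3.0
    wobble_period_s: float = 60.0
    clip_g: float = 8.0

    def step_frequency(self, speed) -> np.ndarray:
        return self.step_freq_base + self.step_freq_slope * np.asarray(speed, float)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    n: int, seed: int, config: Optional[CohortConfig] = None
) -> List[SubjectProfile]:
    """Draw ``n`` subject profiles with the configured covariate marginals.

    Deterministic for fixed ``(n, seed, config)``. Preferred speed declines
    with age and BMI and is higher for men and physically active subjects;
    grip declines with age and tracks walking speed, which — through the
    sex- and BMI-stratified weakness rule — produces frailty at roughly the
    configured prevalence.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    if n == 0:
        return []

    woman = rng.random(n) < cfg.p_woman
    sex = np.where(woman, "woman", "man")

    grp = rng.choice(len(cfg.age_group_probs), size=n, p=cfg.age_group_probs)
    lo = np.array([b[0] for b in cfg.age_group_bounds])[grp]
    hi = np.array([b[1] for b in cfg.age_group_bounds])[grp]
    age = rng.uniform(lo, hi)

    bcat = rng.choice(3, size=n, p=cfg.bmi_category_probs)
    bmi = np.empty(n)
    m = bcat == 0
    bmi[m] = rng.uniform(19.0, 25.0, m.sum())
    m = bcat == 1
    bmi[m] = rng.uniform(25.0, 30.0, m.sum())
    m = bcat == 2
    bmi[m] = np.minimum(30.0 + rng.exponential(3.0, m.sum()), 45.0)

    active = rng.random(n) < cfg.p_active
    mvpa = np.where(
        active,
        150.0 + rng.exponential(120.0, n),
        rng.uniform(0.0, 150.0, n),
    )

    speed = (
        cfg.speed_base
        + cfg.speed_b_man * (~woman)
        + cfg.speed_b_age * (age - 62.0)
        + cfg.speed_b_bmi * (bmi - 26.0)
        + cfg.speed_b_active * active
        + rng.normal(0.0, cfg.speed_noise_sd, n)
    )
    speed = np.clip(speed, *cfg.speed_clip)

    wssd = rng.uniform(*cfg.within_sd_range, n)

    grip = (
        np.where(woman, cfg.grip_base_woman, cfg.grip_base_man)
        + cfg.grip_b_age * (age - 62.0)
        + cfg.grip_b_speed * (speed - 1.3)
        + rng.normal(0.0, 1.0, n) * np.where(woman, cfg.grip_sd_woman, cfg.grip_sd_man)
    )
    grip = np.maximum(grip, 0.0)

    return [
        SubjectProfile(
            subject_id=f"S{i:05d}",
            sex=str(sex[i]),
            age=float(age[i]),
            bmi=float(bmi[i]),
            weekly_mvpa=float(mvpa[i]),
            grip_kg=float(grip[i]),
            preferred_speed_true=float(speed[i]),
            within_subject_speed_sd=float(wssd[i]),
        )
        for i in range(n)
    ]


def cohort_to_frame(profiles: Sequence[SubjectProfile]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in profiles])


# ---------------------------------------------------------------------------
# activity schedules
# ---------------------------------------------------------------------------

def _bout_durations(k: int, rng: np.random.Generator, cfg: ScheduleConfig) -> np.ndarray:
    cat = rng.choice(3, size=k, p=cfg.category_probs)
    d = np.empty(k, dtype=int)
    m = cat == 0
    d[m] = rng.integers(cfg.short_range_s[0], cfg.short_range_s[1] + 1, m.sum())
    m = cat == 1
    d[m] = rng.integers(cfg.medium_range_s[0], cfg.medium_range_s[1] + 1, m.sum())
    m = cat == 2
    d[m] = np.minimum(
        cfg.medium_range_s[1] + 1
        + rng.exponential(cfg.long_excess_mean_s, m.sum()).astype(int),
        cfg.long_max_s,
    )
    return d


def _speed_trace(
    duration_s: int,
    profile: SubjectProfile,
    rng: np.random.Generator,
    cfg: ScheduleConfig,
) -> np.ndarray:
    sd = profile.within_subject_speed_sd
    if duration_s > cfg.medium_range_s[1]:
        sd = sd * cfg.long_sd_multiplier
    mean = profile.preferred_speed_true + rng.normal(0.0, 1.0) * sd
    mean = float(np.clip(mean, *cfg.bout_speed_clip))
    jit_sd = cfg.per_second_jitter_frac * profile.within_subject_speed_sd
    if jit_sd > 0:
        # AR(1): e[t] = rho*e[t-1] + sqrt(1-rho^2)*innov[t], e[0] = innov[0]
        r = cfg.jitter_rho
        x = rng.normal(0.0, jit_sd, duration_s)
        x[1:] *= np.sqrt(1.0 - r * r)
        e = sps.lfilter([1.0], [1.0, -r], x)
    else:
        e = np.zeros(duration_s)
    return np.maximum(mean + e, 0.2)


def _place_in_window(
    events: list,
    win_start: int,
    win_len: int,
    rng: np.random.Generator,
    cfg: ScheduleConfig,
) -> List[Tuple[int, int, str]]:
    """Place (duration, kind) events inside a window with random gaps."""
    placed = []
    order = rng.permutation(len(events))
    kept, total = [], 0
    for idx in order:
        dur = events[idx][0]
        if total + dur + (len(kept) + 1) * cfg.min_gap_s > win_len:
            continue
        kept.append(events[idx])
        total += dur
    if not kept:
        return placed
    slack = win_len - total - (len(kept) + 1) * cfg.min_gap_s
    w = rng.exponential(1.0, len(kept) + 1)
    gaps = cfg.min_gap_s + np.floor(slack * w / w.sum()).astype(int)
    cursor = win_start
    for (dur, kind), gap in zip(kept, gaps[:-1]):
        cursor += int(gap)
        placed.append((cursor, dur, kind))
        cursor += dur
    return placed


def generate_schedule(
    profile: SubjectProfile,
    n_days: int,
    seed: int,
    config: Optional[ScheduleConfig] = None,
) -> ActivitySchedule:
    """Simulate a free-living activity schedule for one subject.

    Each day holds an inactive night block and morning/afternoon (plus an
    occasional evening) active periods; gait-bout durations follow the
    65/30/5 short/medium/long mixture, per-bout mean speed is
    Normal(preferred, within-subject SD) with an inflated SD for long
    bouts, and per-second speeds add a small AR(1) jitter proportional to
    the subject's between-bout SD.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    cfg = config or ScheduleConfig()
    rng = np.random.default_rng(seed)
    events: List[ScheduleEvent] = []
    weights = np.array([w for _, _, w in cfg.active_windows], float)
    weights = weights / weights.sum()
    for day in range(n_days):
        day0 = day * cfg.day_length_s
        n_bouts = max(1, int(rng.poisson(cfg.bouts_per_day_mean)))
        n_act = int(rng.poisson(cfg.nongait_per_day_mean))
        durs = _bout_durations(n_bouts, rng, cfg)
        pool = [(int(d), GAIT) for d in durs] + [
            (int(rng.integers(*cfg.nongait_duration_range_s)), NONGAIT_ACTIVE)
            for _ in range(n_act)
        ]
        assign = rng.choice(len(cfg.active_windows), size=len(pool), p=weights)
        for w_idx, (f0, f1, _) in enumerate(cfg.active_windows):
            win_events = [pool[i] for i in range(len(pool)) if assign[i] == w_idx]
            if not win_events:
                continue
            ws = day0 + int(f0 * cfg.day_length_s)
            wl = int((f1 - f0) * cfg.day_length_s)
            for start, dur, kind in _place_in_window(win_events, ws, wl, rng, cfg):
                trace = (
                    _speed_trace(dur, profile, rng, cfg) if kind == GAIT else None
                )
                events.append(ScheduleEvent(start, dur, kind, trace))
    events.sort(key=lambda e: e.start_s)
    return ActivitySchedule(
        subject_id=profile.subject_id,
        n_days=n_days,
        day_length_s=cfg.day_length_s,
        events=events,
    )


# ---------------------------------------------------------------------------
# raw-signal synthesis
# ---------------------------------------------------------------------------

def _unit_vectors(theta_rad: np.ndarray, phi_rad: np.ndarray) -> np.ndarray:
    st = np.sin(theta_rad)
    return np.stack(
        [st * np.cos(phi_rad), st * np.sin(phi_rad), np.cos(theta_rad)], axis=1
    )


def synthesize_signal(
    schedule: ActivitySchedule,
    seed: int,
    config: Optional[SignalConfig] = None,
) -> SignalRecording:
    """Render an activity schedule into raw tri-axial acceleration.

    The forearm orientation (hence the gravity component seen by the
    device) depends on the activity: roughly vertical during gait, more
    horizontal at rest, with a slow wobble. Gait adds impact and arm-swing
    harmonics along the gravity axis; non-gait activity adds aperiodic
    band-limited movement; white sensor noise is always present. Truth
    channels mirror the schedule exactly.
    """
    cfg = config or SignalConfig()
    schedule.validate()
    rng = np.random.default_rng(seed)
    fs = cfg.sampling_rate
    n_sec = schedule.total_seconds
    n = n_sec * fs

    # per-second posture (polar angle of gravity in the device frame)
    theta_s = np.full(n_sec, np.deg2rad(cfg.posture_deg[2]))
    phi_s = np.full(n_sec, 0.0)
    kind_idx = {GAIT: 0, NONGAIT_ACTIVE: 1, REST: 2}
    for ev in schedule.events:
        sl = slice(ev.start_s, ev.start_s + ev.duration_s)
        base = cfg.posture_deg[kind_idx.get(ev.kind, 2)]
        theta_s[sl] = np.deg2rad(base + rng.normal(0.0, cfg.posture_sd_deg))
        phi_s[sl] = rng.uniform(0.0, 2 * np.pi)
    theta = np.repeat(theta_s, fs)
    phi = np.repeat(phi_s, fs)
    t = np.arange(n) / fs
    theta = theta + np.deg2rad(cfg.wobble_amp_deg) * np.sin(
        2 * np.pi * t / cfg.wobble_period_s + rng.uniform(0, 2 * np.pi)
    )
    theta = np.clip(theta, 0.0, np.pi)
    ghat = _unit_vectors(theta, phi)

    radial = np.ones(n)  # modulation along the gravity axis, in g
    acc = np.zeros((n, 3))

    if cfg.nongait_band_hz[1] >= fs / 2:
        raise ValueError("non-gait band must lie below Nyquist")
    sos = sps.butter(2, cfg.nongait_band_hz, btype="bandpass", fs=fs, output="sos")

    for ev in schedule.events:
        a, b = ev.start_s * fs, (ev.start_s + ev.duration_s) * fs
        if ev.kind == GAIT:
            speed = np.repeat(np.asarray(ev.speed_trace, float), fs)
            f_step = cfg.step_frequency(speed)
            phase = 2 * np.pi * np.cumsum(f_step) / fs + rng.uniform(0, 2 * np.pi)
            a_imp = cfg.impact_amp_base + cfg.impact_amp_slope * speed
            a_sw = cfg.swing_ratio * a_imp
            radial[a:b] += a_imp * np.sin(phase) + a_sw * np.sin(
                phase / 2 + rng.uniform(0, 2 * np.pi)
            )
        elif ev.kind == NONGAIT_ACTIVE:
            raw = rng.normal(0.0, 1.0, (b - a, 3))
            filt = sps.sosfiltfilt(sos, raw, axis=0)
            rms = np.sqrt(np.mean(filt**2))
            if rms > 0:
                filt *= cfg.nongait_rms / rms
            acc[a:b] += filt

    acc += ghat * radial[:, None]
    acc += rng.normal(0.0, cfg.noise_sd, (n, 3))
    np.clip(acc, -cfg.clip_g, cfg.clip_g, out=acc)

    label, speed = schedule.truth_arrays()
    return SignalRecording(
        sampling_rate=fs,
        acceleration=acc,
        truth_label=label,
        truth_speed=speed,
    )


# ---------------------------------------------------------------------------
# direct generative model for the inference layer
# ---------------------------------------------------------------------------

def simulate_association_cohort(
    n: int,
    seed: int,
    effect: float = 0.0,
    metric_name: str = "p95_medium",
    prevalence_intercept: float = -2.55,
) -> Tuple[pd.DataFrame, float]:
    """Cohort whose frailty follows a known logistic model, for calibration
    of the inference layer (type-I error, power, coefficient recovery).

    The named speed-metric column is drawn independently of the base
    covariates on a plausible m/s scale (SD 0.15), and its standardized
    value enters the true linear predictor with coefficient ``-effect``
    (faster walkers are less frail). With ``effect=0`` the metric is a
    pure-noise covariate, giving an exact null for the likelihood-ratio
    test. Returns ``(table, true_coef)`` where ``true_coef`` is the
    coefficient on the metric column itself (per m/s).
    """
    from .clinical_scores import add_covariates

    rng = np.random.default_rng(seed)
    profiles = generate_cohort(n, seed=int(rng.integers(2**31 - 1)))
    table = add_covariates(cohort_to_frame(profiles))
    z = rng.normal(0.0, 1.0, n)
    table[metric_name] = 1.55 + 0.15 * z  # plausible p95-speed scale, m/s

    woman = (table["sex"] == "woman").to_numpy()
    age = table["age"].to_numpy(float)
    bmi = table["bmi"].to_numpy(float)
    active = (table["pa_level"] == "active").to_numpy()
    lin = (
        prevalence_intercept
        + 0.3 * woman
        + 0.05 * (age - 62.0)
        + 0.04 * (bmi - 26.0)
        - 0.3 * active
        - effect * z
    )
    p = 1.0 / (1.0 + np.exp(-lin))
    table["frail"] = rng.random(n) < p
    return table, -effect / 0.15
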