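"""Cohort, schedule and signal generators: contracts and calibration."""

import dataclasses

import numpy as np
import pytest

from realgait.speed_metrics import bout_share
from realgait.synthetic_data import (
    GAIT,
    ActivitySchedule,
    ScheduleConfig,
    ScheduleEvent,
    SubjectProfile,
    cohort_to_frame,
    generate_cohort,
    generate_schedule,
    synthesize_signal,
)


def test_generate_cohort_empty_and_errors():
    assert generate_cohort(0, seed=1) == []
    with pytest.raises(ValueError):
        generate_cohort(-1, seed=1)


def test_generate_cohort_seeding_contract():
    a = generate_cohort(50, seed=9)
    b = generate_cohort(50, seed=9)
    c = generate_cohort(50, seed=10)
    assert a == b
    assert [p.grip_kg for p in a] != [p.grip_kg for p in c]


def test_cohort_marginals():
    frame = cohort_to_frame(generate_cohort(2809, seed=4))
    woman_pct = 100.0 * (frame["sex"] == "woman").mean()
    assert abs(woman_pct - 53.7) < 2.0
    assert frame["age"].between(45, 95).all()
    assert frame["preferred_speed_true"].between(0.4, 2.2).all()
    assert (frame["grip_kg"] >= 0).all()


def test_cohort_effect_directions():
    """Preferred speed declines with age/BMI, higher for men and active."""
    frame = cohort_to_frame(generate_cohort(4000, seed=8))
    men = frame[frame.sex == "man"]["preferred_speed_true"].mean()
    women = frame[frame.sex == "woman"]["preferred_speed_true"].mean()
    assert men > women
    young = frame[frame.age < 55]["preferred_speed_true"].mean()
    old = frame[frame.age >= 75]["preferred_speed_true"].mean()
    assert young > old
    assert np.corrcoef(frame.bmi, frame.preferred_speed_true)[0, 1] < 0


def test_profile_invariants():
    with pytest.raises(ValueError):
        SubjectProfile("x", "man", 30, 25, 0, 30, 1.3, 0.1)  # age
    with pytest.raises(ValueError):
        SubjectProfile("x", "man", 60, 25, 0, 30, 3.0, 0.1)  # speed


def test_schedule_contract(profile):
    with pytest.raises(ValueError):
        generate_schedule(profile, 0, seed=1)
    sched = generate_schedule(profile, 13, seed=1)
    # non-overlapping, sorted events
    prev_end = -1
    for ev in sched.events:
        assert ev.start_s > prev_end
        prev_end = ev.start_s + ev.duration_s - 1
    # every day contains at least one gait event
    gait_days = {
        ev.start_s // sched.day_length_s for ev in sched.events if ev.kind == GAIT
    }
    assert gait_days == set(range(13))
    # speed traces: one positive speed per second
    for ev in sched.events:
        if ev.kind == GAIT:
            assert len(ev.speed_trace) == ev.duration_s
            assert (ev.speed_trace > 0).all()


def test_schedule_zero_within_subject_sd(profile):
    prof = dataclasses.replace(profile, within_subject_speed_sd=0.0)
    sched = generate_schedule(prof, 2, seed=5)
    for ev in sched.events:
        if ev.kind == GAIT:
            assert np.allclose(ev.speed_trace, prof.preferred_speed_true)


def test_schedule_bout_duration_mixture():
    """Mean short-bout share near the 65% design value (small-n version)."""
    profiles = generate_cohort(30, seed=21)
    shares = []
    for i, p in enumerate(profiles):
        sched = generate_schedule(p, 13, seed=300 + i)
        shares.append(bout_share(sched.gait_bouts()["duration_s"].to_numpy())["short"])
    assert abs(np.mean(shares) - 65.0) < 5.0


def _single_bout_schedule(profile, duration=60, speed=1.2, day_s=600):
    trace = np.full(duration, float(speed))
    events = [ScheduleEvent(100, duration, GAIT, trace)]
    return ActivitySchedule(profile.subject_id, 1, day_s, events)


def test_synthesize_signal_counts(profile):
    sched = _single_bout_schedule(profile)
    rec = synthesize_signal(sched, seed=2)
    assert rec.acceleration.shape == (600 * 50, 3)
    assert rec.truth_label.sum() == 60
    assert np.isfinite(rec.truth_speed[100:160]).all()
    # conservation: scheduled gait seconds == truth gait seconds
    assert rec.truth_label.sum() == sum(
        ev.duration_s for ev in sched.events if ev.kind == GAIT
    )


def test_synthesize_signal_reproducible(profile):
    sched = _single_bout_schedule(profile)
    a = synthesize_signal(sched, seed=3).acceleration
    b = synthesize_signal(sched, seed=3).acceleration
    assert np.array_equal(a, b)


def test_rest_only_signal_is_gravity_plus_noise(profile):
    events = []
    sched = ActivitySchedule(profile.subject_id, 1, 120, events)
    rec = synthesize_signal(sched, seed=7)
    norm = np.linalg.norm(rec.acceleration, axis=1)
    assert abs(norm.mean() - 1.0) < 0.02
    assert norm.std() < 3 * 0.03  # a few noise SDs


def test_gait_second_dominant_frequency(profile):
    """FFT oracle: enhanced-norm peak at step_freq = 1.45 + 0.35 * speed."""
    from realgait.signal_features import enhance_signal

    sched = _single_bout_schedule(profile, duration=60, speed=1.0)
    rec = synthesize_signal(sched, seed=11)
    enhanced = enhance_signal(rec)
    seg = enhanced[110 * 50 : 140 * 50]  # 30 s inside the bout
    freqs = np.fft.rfftfreq(len(seg), 1 / 50)
    spec = np.abs(np.fft.rfft(seg - seg.mean()))
    dom = freqs[spec.argmax()]
    assert dom == pytest.approx(1.80, abs=freqs[1] - freqs[0] + 1e-9)


def test_overlapping_events_rejected(profile):
    tr = np.full(30, 1.2)
    with pytest.raises(ValueError):
        ActivitySchedule(
            "x",
            1,
            600,
            [ScheduleEvent(0, 30, GAIT, tr), ScheduleEvent(10, 30, GAIT, tr)],
        )
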