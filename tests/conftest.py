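import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from realgait.synthetic_data import (
    ScheduleConfig,
    SubjectProfile,
    generate_cohort,
    generate_schedule,
    synthesize_signal,
)


@pytest.fixture(scope="session")
def profile():
    return SubjectProfile(
        subject_id="T0",
        sex="woman",
        age=60.0,
        bmi=24.0,
        weekly_mvpa=200.0,
        grip_kg=30.0,
        preferred_speed_true=1.3,
        within_subject_speed_sd=0.10,
    )


@pytest.fixture(scope="session")
def bench_recording(profile):
    """One signal-level subject over a compressed 1 h day."""
    cfg = ScheduleConfig.signal_benchmark(1.0)
    schedule = generate_schedule(profile, 1, seed=404, config=cfg)
    return synthesize_signal(schedule, seed=405), schedule


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(50, seed=7)
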