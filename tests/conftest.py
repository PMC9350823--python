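import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dosefreq import PatientProfile, SimConfig, make_task_catalog, simulate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete simulated cohort (sessions + profiles)."""
    config = SimConfig(n_patients_per_group=3, n_domains=2, n_weeks=11, rng_seed=7)
    sessions, profiles = simulate_cohort(config)
    return config, sessions, profiles


@pytest.fixture
def able_profile():
    """Patient far above every task difficulty: accuracy ~ 1 everywhere."""
    return PatientProfile(
        patient_id="able", age=60.0, sex="female", months_post_stroke=3.0,
        ability=100.0, learning_rate=0.0, target_days_per_week=5)


@pytest.fixture
def struggling_profile():
    """Patient far below the easiest task: accuracy ~ 0 everywhere."""
    return PatientProfile(
        patient_id="struggling", age=60.0, sex="male", months_post_stroke=12.0,
        ability=-100.0, learning_rate=0.0, target_days_per_week=3)


@pytest.fixture
def catalog():
    return make_task_catalog(1, 20, 0.5)[0]


def sessions_frame(rows):
    """Helper: build a session-log frame from (pid, dom, date, rank, acc, min)."""
    return pd.DataFrame(
        rows, columns=["patient_id", "domain_id", "date", "task_rank",
                       "accuracy", "minutes"])
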