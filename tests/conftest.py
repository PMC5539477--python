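import numpy as np
import pytest

from wearhrv.generate import (
    SessionSchedule,
    generate_cohort,
    make_subject_profile,
    simulate_minute_table,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def profile():
    return make_subject_profile("S01", np.random.default_rng(7))


@pytest.fixture(scope="session")
def fast_table():
    """Feature-level default cohort: 13 subjects, full schedule."""
    return simulate_minute_table(seed=11)


@pytest.fixture(scope="session")
def small_raw_cohort():
    """Raw-signal cohort small enough for per-test extraction: 3 subjects,
    shortened sessions (1-min statics, 2-min dynamics)."""
    schedule = SessionSchedule(entries=(
        ("SI", 1), ("ST", 1), ("WK", 2), ("REST", 1),
        ("AS", 2), ("RU", 2), ("REST", 1),
    ))
    return generate_cohort(n_subjects=3, schedule=schedule, seed=5)
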