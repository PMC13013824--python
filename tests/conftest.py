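import numpy as np
import pytest

from tempope.task import ScheduleConfig, generate_schedule, schedule_to_events


@pytest.fixture(scope="session")
def default_schedule():
    return generate_schedule(seed=7)


@pytest.fixture(scope="session")
def default_events(default_schedule):
    return schedule_to_events(default_schedule)


@pytest.fixture(scope="session")
def small_schedule():
    """A shortened two-run schedule for fast design/GLM tests."""
    cfg = ScheduleConfig(
        run1_normal_per_condition=8,
        run2_normal_per_condition=6,
        run2_catch_per_condition=3,
    )
    return generate_schedule(cfg, seed=3)


@pytest.fixture(scope="session")
def small_events(small_schedule):
    return schedule_to_events(small_schedule)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
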