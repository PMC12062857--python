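import numpy as np
import pytest

from volbandit.agents import CohortConfig, generate_cohort
from volbandit.models import default_family, get_spec
from volbandit.task import TaskConfig, generate_schedule


@pytest.fixture(scope="session")
def family():
    return default_family()


@pytest.fixture(scope="session")
def winner_spec():
    return get_spec("M06")


@pytest.fixture(scope="session")
def default_schedule():
    return generate_schedule(TaskConfig(seed=7))


@pytest.fixture(scope="session")
def plain_schedule():
    """Default structure without coin magnitudes."""
    return generate_schedule(TaskConfig(seed=7, magnitude_rule="none"))


@pytest.fixture(scope="session")
def small_cohort():
    """10-participant cohort with behaviour, no random responders."""
    cfg = CohortConfig(n_mt=6, n_nmt=4, random_responder_fraction=0.0, seed=21)
    return generate_cohort(cfg)
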