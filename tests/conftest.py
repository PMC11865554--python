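import numpy as np
import pytest

from tacit.gridworld import BOARD_4X4, GoalConfiguration
from tacit.planner import ModelParams
from tacit.synthetic import DEFAULT_GROUP_PARAMS, SyntheticSpec, simulate_cohort_records


@pytest.fixture(scope="session")
def board():
    return BOARD_4X4


@pytest.fixture(scope="session")
def indirect_config():
    # receiver goal off every shortest start->sender-goal path
    return GoalConfiguration(start=(1, 1), sender_goal=(1, 3), receiver_goal=(3, 0))


@pytest.fixture(scope="session")
def direct_config():
    # receiver goal on the straight east path
    return GoalConfiguration(start=(1, 1), sender_goal=(1, 3), receiver_goal=(1, 2))


@pytest.fixture(scope="session")
def table1_params() -> ModelParams:
    return DEFAULT_GROUP_PARAMS["surprise"]


@pytest.fixture(scope="session")
def small_cohort():
    """8 surprise-variant subjects x 40 trials with receiver choices."""
    spec = SyntheticSpec(n_subjects=8, trials_per_subject=40, rng_seed=11)
    return simulate_cohort_records(spec)


@pytest.fixture(scope="session")
def small_cohort_by_subject(small_cohort):
    subs = {}
    for rec in small_cohort:
        subs.setdefault(rec.subject_id, []).append((rec.config, rec.message))
    return [subs[k] for k in sorted(subs)]


def all_board_symmetries():
    """The 8 symmetries of the square board as state maps."""
    n = 4

    def make(fn):
        return lambda s: fn(*s)

    return [
        make(lambda r, c: (r, c)),
        make(lambda r, c: (c, n - 1 - r)),
        make(lambda r, c: (n - 1 - r, n - 1 - c)),
        make(lambda r, c: (n - 1 - c, r)),
        make(lambda r, c: (r, n - 1 - c)),
        make(lambda r, c: (n - 1 - r, c)),
        make(lambda r, c: (c, r)),
        make(lambda r, c: (n - 1 - c, n - 1 - r)),
    ]


# deterministic property testing: identical examples on every run
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")
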