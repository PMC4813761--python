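import numpy as np
import pytest

from countermand.sim.race import RaceParams, TaskConfig, simulate_behavior_session
from countermand.behavior import classify_trials


@pytest.fixture(scope="session")
def long_session():
    """Drift-free session with ~2,500 signal trials (shared, read-only)."""
    cfg = TaskConfig(n_trials_per_block=5000, n_blocks=1)
    return simulate_behavior_session(cfg, RaceParams(), seed=11)


@pytest.fixture(scope="session")
def long_classified(long_session):
    return classify_trials(long_session)


@pytest.fixture(scope="session")
def medium_session():
    """Default-size session (155 x 2 trials)."""
    return simulate_behavior_session(TaskConfig(), RaceParams(), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
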