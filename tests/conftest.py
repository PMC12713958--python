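import sys
from pathlib import Path

import numpy as np
import pytest

from audiopvt import TestConfig, build_schedule

sys.path.insert(0, str(Path(__file__).parent))  # for the shared oracles module


@pytest.fixture
def rng():
    return np.random.default_rng(20230721)


@pytest.fixture
def simple_config():
    return TestConfig(repetitions=10, min_delay=500.0, max_delay=1500.0, seed=7)


@pytest.fixture
def simple_schedule(simple_config):
    return build_schedule(simple_config)


@pytest.fixture
def gng_config():
    return TestConfig(
        paradigm="go_no_go", repetitions=40, min_delay=1000.0, max_delay=1000.0, seed=11
    )


@pytest.fixture
def gng_schedule(gng_config):
    return build_schedule(gng_config)


def random_session(rng, n_trials=None, go_no_go=None):
    """A random small schedule plus a random press stream for oracle replay."""
    if n_trials is None:
        n_trials = int(rng.integers(1, 9))
    if go_no_go is None:
        go_no_go = bool(rng.integers(0, 2))
    config = TestConfig(
        paradigm="go_no_go" if go_no_go else "simple_rt",
        repetitions=n_trials,
        min_delay=300.0,
        max_delay=300.0 if go_no_go else 900.0,
        tone_duration=100.0,
        min_response_time=float(rng.choice([0.0, 100.0, 200.0])),
        nogo_fraction=float(rng.uniform(0.0, 0.6)),
    )
    schedule = build_schedule(config, seed=int(rng.integers(2**31)))
    n_press = int(rng.poisson(1.2 * n_trials))
    presses = rng.uniform(0.0, schedule.session_end * 1.02, size=n_press)
    return config, schedule, np.sort(presses)
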