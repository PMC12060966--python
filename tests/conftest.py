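import numpy as np
import pytest

from banditexplore.agents import KalmanParams, simulate_session
from banditexplore.task_env import WalkConfig, generate_walk, generate_walks


@pytest.fixture(scope="session")
def default_walk():
    return generate_walk(WalkConfig(), seed=1)


@pytest.fixture(scope="session")
def walk_pool():
    """A handful of accepted 300-trial walks shared across tests."""
    return generate_walks(6, seed=202)


@pytest.fixture(scope="session")
def kalman_session(default_walk):
    params = KalmanParams(phi=0.3, omega=0.2, beta=5.0)
    return simulate_session("kalman", params, default_walk, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
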