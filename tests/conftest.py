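import numpy as np
import pytest

from psychocompare.configs import get_experiment
from psychocompare.observers import SimulatedObserver
from psychocompare.psychometric import PsychometricParams


@pytest.fixture(scope="session")
def exp1():
    return get_experiment(1)


@pytest.fixture(scope="session")
def exp2():
    return get_experiment(2)


@pytest.fixture(scope="session")
def exp3():
    return get_experiment(3)


@pytest.fixture
def make_observer():
    def _make(m=1.6, sd=0.08, lapse=0.01, seed=0, drift=(1.0, 1.0, 1.0)):
        return SimulatedObserver(
            true_params=PsychometricParams(m, sd, lapse), drift=drift, rng_seed=seed
        )

    return _make


class CoinFlipObserver:
    """Responds "yes" with probability 0.5 regardless of the stimulus."""

    def __init__(self, seed: int):
        self._rng = np.random.default_rng(seed)

    def respond(self, x, block=1):
        return int(self._rng.random() < 0.5)


@pytest.fixture
def coin_flip_observer():
    return CoinFlipObserver
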