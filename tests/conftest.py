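import numpy as np
import pytest

from fatiguelfp import SpikeTrain, default_spec
from fatiguelfp.core import EpochWindow


@pytest.fixture(scope="session")
def spec_pre():
    """Default synthetic spec, deterministic seed."""
    return default_spec({"seed": 11})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def poisson_train(rng, rate, duration, region="M1", unit=0):
    n = rng.poisson(rate * duration)
    times = np.unique(np.sort(rng.uniform(0.0, duration, n)))
    return SpikeTrain(region, unit, times, (0.0, duration))


def epoch(duration, label="pre", start=0.0):
    return EpochWindow(label, start, start + duration)


@pytest.fixture()
def make_poisson_train():
    return poisson_train


@pytest.fixture()
def make_epoch():
    return epoch
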