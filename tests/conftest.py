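import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from duplifate import MechanismParams, SimConfig, Timeline, simulate_timeline


@pytest.fixture(scope="session")
def nonfunc():
    return MechanismParams.nonfunctionalization(0.2, 0.8)


@pytest.fixture(scope="session")
def neo():
    return MechanismParams.neofunctionalization(0.2, 0.8)


@pytest.fixture(scope="session")
def sub():
    return MechanismParams.subfunctionalization(0.2, 0.8, 5.0)


@pytest.fixture(scope="session")
def trio(nonfunc, neo, sub):
    return {"nonfunc": nonfunc, "neo": neo, "sub": sub}


@pytest.fixture(scope="session")
def small_timeline():
    """A fixed 5-event timeline used across density tests."""
    return Timeline.from_times([1.0, 2.5, 4.0, 7.0, 9.0], T=10.0, n0=2)


@pytest.fixture(scope="session")
def simulated_timeline(nonfunc):
    """One reproducible simulated timeline at the matched-onset parameters."""
    cfg = SimConfig(params=nonfunc, model="time", T=10.0, n0=2, nT=32, seed=123)
    return simulate_timeline(cfg, np.random.default_rng(123))
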