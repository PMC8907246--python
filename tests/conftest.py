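import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

from herdspace.config import HerdConfig
from herdspace.simulate import child_streams, simulate_roster


@pytest.fixture(scope="session")
def herd_config():
    return HerdConfig(n_pairs=20, seed=101)


@pytest.fixture(scope="session")
def rngs(herd_config):
    return child_streams(herd_config.seed)


@pytest.fixture(scope="session")
def roster(herd_config):
    return simulate_roster(herd_config, np.random.default_rng(101))


def make_roster(n_pairs=10, seed=0, **kw):
    cfg = HerdConfig(n_pairs=n_pairs, seed=seed, **kw)
    return simulate_roster(cfg, np.random.default_rng(seed)), cfg


@pytest.fixture(scope="session")
def tiny_tte():
    """Hand-checkable survival fixture: 3 uncensored times in one group."""
    return pd.DataFrame({
        "cow_lactation_id": ["a", "b", "c"],
        "group": ["control"] * 3,
        "parity_group": ["primiparous-control"] * 3,
        "time": [1.0, 2.0, 3.0],
        "event": [1, 1, 1],
    })
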