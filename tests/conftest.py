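import numpy as np
import pytest

import twinirt as t
from twinirt.simulate import SCENARIO_PARAMS


@pytest.fixture(scope="session")
def scenario_params():
    """The generative truth shared by all scenario presets."""
    return SCENARIO_PARAMS


@pytest.fixture(scope="session")
def tiny_dataset():
    """A miniature simulated dataset (50 pairs, 10 items) for fast fits."""
    cfg = t.scenario1(n_pairs=50, n_items=10, n_replications=1, seed=1234)
    return t.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """A mid-sized dataset (400 pairs, 20 items) for single-fit checks."""
    cfg = t.scenario1(n_pairs=400, n_items=20, n_replications=1, seed=99)
    return t.simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
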