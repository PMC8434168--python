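import numpy as np
import pytest

import exerscreen as ex


@pytest.fixture(scope="session")
def default_config():
    return ex.CohortConfig(seed=0)


@pytest.fixture(scope="session")
def study(default_config):
    """Full default trial simulation, shared across the suite."""
    return ex.run_study(default_config)


@pytest.fixture(scope="session")
def small_study():
    """A reduced cohort for the slower model-fitting tests."""
    cfg = ex.CohortConfig(group_sizes={"CN": 12, "MCI": 18, "MD": 8}, seed=3)
    return ex.run_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
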