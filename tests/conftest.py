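import numpy as np
import pytest

from devtraject import envgen


@pytest.fixture(scope="session")
def env_set():
    """The task's default set of 40 smooth environments."""
    return envgen.generate_environment_set(40, seed=123)


@pytest.fixture(scope="session")
def small_envs():
    """A cheap 10-environment set for simulation-heavy tests."""
    return envgen.generate_environment_set(10, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
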