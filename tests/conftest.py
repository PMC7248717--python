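import numpy as np
import pytest

from mindwander import simulate


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study shared by read-only tests."""
    return simulate.simulate_study(simulate.small_config(n_participants=4, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
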