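import numpy as np
import pytest

from tooltrans import SimConfig, run_simulation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def social_run():
    """One complete social-learning run at the default study conditions."""
    return run_simulation(SimConfig(condition="social", rng_seed=77))


@pytest.fixture(scope="session")
def inheritance_run():
    """One complete inheritance-condition run at the default conditions."""
    return run_simulation(SimConfig(condition="inheritance", rng_seed=77))
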