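import numpy as np
import pytest

from pseudohealthy import PhantomSpec, make_healthy_phantom, sample_training_mask


@pytest.fixture(scope="session")
def phantom64():
    return make_healthy_phantom(PhantomSpec(size=64, seed=1))


@pytest.fixture(scope="session")
def mask64(phantom64):
    return sample_training_mask((64, 64), phantom64.foreground(), seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
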