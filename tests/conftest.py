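import numpy as np
import pytest

from cada.phantom import PhantomSpec, generate_phantom
from cada.volume_io import Volume


@pytest.fixture(scope="session")
def control_phantom():
    """One control-like phantom volume with ground truth (session-cached)."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def pd_phantom():
    """A PD-like phantom with asymmetric damage and programmed rotation."""
    return generate_phantom(PhantomSpec(seed=12, damage=(0.7, 0.35)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_volume(rng):
    data = rng.uniform(0.5, 2.0, size=(16, 16, 12))
    return Volume(data, spacing=(2.0, 2.0, 2.0),
                  affine=np.diag([2.0, 2.0, 2.0, 1.0]), id="small")
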