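import numpy as np
import pytest

from mdmunet.blocks import BlockConfig
from mdmunet.synthetic import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """A desk-scale block configuration (8 channels keeps every test fast)."""
    return BlockConfig(channels=8)


@pytest.fixture(scope="session")
def tiny_case():
    """A 32^3 phantom with organ and tumor labels present."""
    spec = PhantomSpec(
        shape=(32, 32, 32),
        organ_axes=(7.0, 12.0, 8.0),
        tumor_radius_range=(2.5, 4.0),
        seed=7,
    )
    case = generate_phantom(spec)
    assert set(np.unique(case.labels)) == {0, 1, 2}
    return case
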