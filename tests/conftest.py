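import numpy as np
import pytest

from pairsift import SyntheticSpec, generate


@pytest.fixture(scope="session")
def fixture_data():
    """Default desk-scale planted-block dataset (seed 1)."""
    return generate(SyntheticSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
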