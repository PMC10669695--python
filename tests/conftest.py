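import numpy as np
import pytest
from hypothesis import settings

from dwigrade.signal_models import BScheme

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scheme() -> BScheme:
    return BScheme()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
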