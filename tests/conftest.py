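import numpy as np
import pytest

from hopfield3 import ModelParams


@pytest.fixture(scope="session")
def p0() -> ModelParams:
    """Default parameters (stability-analysis condition: beta2=1.7, i1=0)."""
    return ModelParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
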