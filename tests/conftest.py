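import numpy as np
import pytest

from hygrocap import ModelParams, ProfileSpec, canonical_profile


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def canonical():
    """Default canonical graded profile (seed 1)."""
    return canonical_profile(ProfileSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
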