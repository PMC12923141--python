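import numpy as np
import pytest
from hypothesis import settings

from coevrisk import ModelParams, get_preset, sample_params

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# upper edge roots of the baseline game (N=8, M=5, b=2), frozen from an
# independent polynomial-root computation of 70 x^4 (1-x)^3 = c0 / b
X1T = 0.355848006632605
X2T = 0.769742501343225
X1B = 0.238489001163511
X2B = 0.862906979808108


@pytest.fixture(scope="session")
def base_params() -> ModelParams:
    return get_preset("monostable")


@pytest.fixture(scope="session")
def random_params() -> list[ModelParams]:
    return sample_params(20260922, 300)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
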