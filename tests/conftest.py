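import numpy as np
import pytest

from ligafib import ModelParams

# Fitted parameter sets reported for the two study specimens (healthy "A",
# osteoarthritic "B"); used throughout as generating truths.
SAMPLE_A = ModelParams(E_f=100.0017, beta=2.0143, delta=0.2450)
SAMPLE_B = ModelParams(E_f=0.5243, beta=4.2552, delta=0.1190)


@pytest.fixture(scope="session")
def sample_a() -> ModelParams:
    return SAMPLE_A


@pytest.fixture(scope="session")
def sample_b() -> ModelParams:
    return SAMPLE_B


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
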