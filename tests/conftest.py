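import numpy as np
import pytest

from flyforget.costs import CostModel
from flyforget.environment import EnvParams, ExtEnvParams
from flyforget.policies import DPConfig


@pytest.fixture
def env() -> EnvParams:
    """Default symmetric environment: conditioned dwell 20 bins, p_n ~ 0.83."""
    return EnvParams()


@pytest.fixture
def ext_env() -> ExtEnvParams:
    return ExtEnvParams()


@pytest.fixture
def costs() -> CostModel:
    return CostModel()


@pytest.fixture
def dp_cfg() -> DPConfig:
    return DPConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
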