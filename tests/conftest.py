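import numpy as np
import pytest

from surfann import PipelineConfig, ResidueMassTable
from surfann import examples as ex


@pytest.fixture(scope="session")
def table() -> ResidueMassTable:
    return ResidueMassTable.default()


@pytest.fixture(scope="session")
def nominal_cfg() -> PipelineConfig:
    return PipelineConfig.nominal()


@pytest.fixture(scope="session")
def default_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


@pytest.fixture
def c12(nominal_cfg):
    return ex.c12_spectrum()


@pytest.fixture
def c13(nominal_cfg):
    return ex.c13_spectrum()
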