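import numpy as np
import pytest

from presyn import AnalysisConfig, SimParams, standard_train_protocol


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def protocol():
    return standard_train_protocol()


@pytest.fixture
def det_params():
    return SimParams(deterministic=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
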