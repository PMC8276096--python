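import numpy as np
import pytest

from sclc_cea import CostEffectivenessModel, ParametricSurvival, default_config

# curves of the published base case, reused across test modules
AEP_OS = ParametricSurvival("loglogistic", (0.003072, 2.297440))
AEP_PFS = ParametricSurvival("loglogistic", (0.008895, 2.852489))
EP_OS = ParametricSurvival("weibull", (0.016073, 1.593409))
EP_PFS = ParametricSurvival("weibull", (0.042826, 1.712046))


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def model(config):
    return CostEffectivenessModel(config)


@pytest.fixture(scope="session")
def results(model):
    return model.fit()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210629)
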