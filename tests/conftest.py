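import numpy as np
import pytest

from nestedrace.params import ModulationSpec, ProcessParams, SimConfig, TaskDesign
from nestedrace.presets import REACTIVE_PARAMS


@pytest.fixture(scope="session")
def reactive_design() -> TaskDesign:
    return TaskDesign.reactive()


@pytest.fixture(scope="session")
def proactive_design() -> TaskDesign:
    return TaskDesign.proactive()


@pytest.fixture(scope="session")
def dpm_params() -> ProcessParams:
    return REACTIVE_PARAMS["dpm"]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


#: effectively noise-free diffusion for closed-form checks
TINY_SIGMA = 1e-9


@pytest.fixture(scope="session")
def noise_free_cfg() -> SimConfig:
    return SimConfig(dt=0.001, deadline=0.650)
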