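import numpy as np
import pytest

from racea.cohort import CohortSpec
from racea.config import build_model_config, load_config
from racea.markov import ModelConfig
from racea.records import CoreSet


@pytest.fixture(scope="session")
def packaged_config() -> dict:
    return load_config()


@pytest.fixture(scope="session")
def model_config(packaged_config) -> ModelConfig:
    return build_model_config(packaged_config)


@pytest.fixture()
def small_spec() -> CohortSpec:
    return CohortSpec(n_per_arm=40, seed=123)


def coreset(sjc=4, tjc=6, stiffness=30.0, vas=5.0, haq=1.0, esr=30.0,
            crp=10.0, rf=50.0, das28=None) -> CoreSet:
    return CoreSet(sjc28=sjc, tjc28=tjc, stiffness_min=stiffness, vas=vas,
                   haq=haq, esr=esr, crp=crp, rf=rf, das28=das28)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
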