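import numpy as np
import pytest

from atcost import (
    CompetitionModel,
    DrugEffectParams,
    PopulationParams,
    SimConfig,
    default_invitro_model,
    default_invivo_model,
)


@pytest.fixture
def invitro_model() -> CompetitionModel:
    return default_invitro_model()


@pytest.fixture
def invivo_model() -> CompetitionModel:
    return default_invivo_model()


@pytest.fixture
def exp_phase_model() -> CompetitionModel:
    """Competition model far below carrying capacity (pure exponential
    regime over the default sampling window)."""
    return CompetitionModel(
        PopulationParams(0.5, 1e9, "sensitive"),
        PopulationParams(0.42, 1e9, "resistant"),
        alpha_sr=1.0,
        alpha_rs=1.0,
    )


@pytest.fixture
def drug() -> DrugEffectParams:
    return DrugEffectParams()


@pytest.fixture
def noiseless_config() -> SimConfig:
    return SimConfig(seed=11, noise_cv=0.0, cn_noise_sd=0.0)


@pytest.fixture
def default_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture
def dense_times() -> tuple:
    return tuple(float(t) for t in np.linspace(0.0, 30.0, 30))
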