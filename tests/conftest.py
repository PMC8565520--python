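import numpy as np
import pytest

from dbserp import PipelineConfig, make_montage
from dbserp.simulate import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def montage64():
    return make_montage(64)


@pytest.fixture(scope="session")
def montage128():
    return make_montage(128)


@pytest.fixture(scope="session")
def short_session(montage64):
    """One default-noise ZI session, 60 s (300 trials), fixed seed."""
    cfg = SimulationConfig(duration_s=60.0)
    return simulate_session(cfg, "ZI", seed=11, montage=montage64)


@pytest.fixture(scope="session")
def noiseless_session(montage64):
    """Evoked field + artifact only (no background), 20 s, fixed seed."""
    cfg = SimulationConfig(
        duration_s=20.0,
        noise_pink_sd_uv=0.0,
        noise_white_sd_uv=0.0,
        noise_alpha_sd_uv=0.0,
    )
    return simulate_session(cfg, "ZI", seed=5, montage=montage64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def config():
    return PipelineConfig()
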