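import pytest

from regonset.config import PipelineConfig
from regonset.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def sim():
    """One default synthetic study, shared read-only across tests."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_noiseless():
    """Same study conditions with all expression/KO noise switched off."""
    return simulate(SimConfig(seed=11, expression_noise_sd=0.0, ko_noise_sd=0.0))


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("simdir")
    simulate(SimConfig(seed=11), out)
    return out
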