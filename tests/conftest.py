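import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from osteosim import BMUParams, MineralizationLaw, SimulationConfig, SiteSpec
from osteosim.tissue import TissueConstants

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants() -> TissueConstants:
    return TissueConstants()


@pytest.fixture(scope="session")
def bmu() -> BMUParams:
    return BMUParams()


@pytest.fixture(scope="session")
def law() -> MineralizationLaw:
    return MineralizationLaw()


@pytest.fixture(scope="session")
def base_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def single_site_config() -> SimulationConfig:
    """One transition-zone site: the fastest configuration that still
    exercises the full feedback loop."""
    return SimulationConfig(sites=(SiteSpec("transition", 1.0, 0.6),))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
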