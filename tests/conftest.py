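import pytest
from hypothesis import HealthCheck, settings

import longbranch as lb

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def zone_model():
    """The study's GTR parameters without indels (unit-test default)."""
    return lb.GTRModel.zone_study(indel_rate=0.0)


@pytest.fixture(scope="session")
def gapped_model():
    """The study's GTR parameters including the indel process."""
    return lb.GTRModel.zone_study()


@pytest.fixture(scope="session")
def jc_model():
    return lb.GTRModel.jukes_cantor()


@pytest.fixture(scope="session")
def six_taxa():
    return tuple(f"T{i}" for i in range(1, 7))
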