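import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def geometry():
    from lungstretch import MembraneGeometry

    return MembraneGeometry()  # a = 1.26 cm (5 cm^2), t = 5 um


@pytest.fixture
def chamber():
    from lungstretch import ChamberConfig

    return ChamberConfig()  # P0 = 98.0 kPa, V0 = 30 mL
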