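import pytest
from hypothesis import HealthCheck, settings

from fibercoip import build_profiles, load_fixture, load_interactome_profiles

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def synthase_profiles():
    """The four CESAs and the CALS with their blank/treated counts."""
    return build_profiles(load_fixture("table2"))


@pytest.fixture(scope="session")
def interactome_profiles():
    """All 19 proteins reproducibly detected across the three pull-downs."""
    return load_interactome_profiles()
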