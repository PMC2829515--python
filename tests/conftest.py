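import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


from homeocaps.digest import DiagnosticAssay, GelBandSet, GelConfig, RestrictionEnzyme


@pytest.fixture
def gel() -> GelConfig:
    return GelConfig()


@pytest.fixture
def simple_assay(gel) -> DiagnosticAssay:
    """A hand-built informative assay: maternal {120, 80}, paternal {200}."""
    return DiagnosticAssay(
        locus_id="L1",
        enzyme=RestrictionEnzyme("EcoRI", "GAATTC", 1),
        maternal_bands=GelBandSet((120, 80)),
        paternal_bands=GelBandSet((200,)),
        maternal_diagnostic=GelBandSet((120, 80)),
        paternal_diagnostic=GelBandSet((200,)),
        gel=gel,
    )
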