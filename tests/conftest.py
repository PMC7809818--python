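import pytest
from hypothesis import HealthCheck, settings

from mitocomp import GeneticCode, Mitogenome, tables
from mitocomp.synthetic_data import GenomeSpec, generate_mitogenome

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def table2_genome() -> Mitogenome:
    """Coordinate-only record of the reference annotation (no sequence)."""
    return Mitogenome(id="MT259034", length=16_636, circular=True,
                      features=tables.canonical_features())


@pytest.fixture(scope="session")
def synthetic_genome() -> Mitogenome:
    """One default synthetic genome, shared across tests."""
    return generate_mitogenome(GenomeSpec(seed=11))


@pytest.fixture(scope="session")
def code() -> GeneticCode:
    return GeneticCode()
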