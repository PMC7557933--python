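import pytest
from hypothesis import HealthCheck, settings

import hrdkit

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixtures():
    """The four expressed study peptides."""
    return hrdkit.load_fixtures()


@pytest.fixture(scope="session")
def by_id(fixtures):
    return {d.id: d for d in fixtures}


@pytest.fixture
def fixture_fasta(tmp_path, fixtures):
    path = tmp_path / "fixtures.fasta"
    hrdkit.write_fasta(fixtures, path)
    return path
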