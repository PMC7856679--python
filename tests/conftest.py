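import io

import pytest

from genesymcheck.checker import CheckOptions
from genesymcheck.excel import extend_map_with_mogrifications
from genesymcheck.fixtures import FixtureSpec, generate_hgnc_fixture, generate_mgi_fixture
from genesymcheck.map_io import parse_hgnc, parse_mgi


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(n_approved=5, seed=7)


@pytest.fixture(scope="session")
def hgnc_fixture(fixture_spec):
    """(file text, truth table) for a small synthetic HGNC file."""
    return generate_hgnc_fixture(fixture_spec)


@pytest.fixture(scope="session")
def mgi_fixture(fixture_spec):
    return generate_mgi_fixture(fixture_spec)


@pytest.fixture(scope="session")
def human_map(hgnc_fixture):
    return parse_hgnc(io.StringIO(hgnc_fixture[0]))


@pytest.fixture(scope="session")
def mouse_map(mgi_fixture):
    return parse_mgi(io.StringIO(mgi_fixture[0]))


@pytest.fixture(scope="session")
def human_map_ext(human_map):
    """Human fixture map including the mogrification reversal index."""
    return extend_map_with_mogrifications(human_map)


@pytest.fixture(scope="session")
def mouse_map_ext(mouse_map):
    return extend_map_with_mogrifications(mouse_map)


@pytest.fixture
def human_opts():
    return CheckOptions(species="human")


@pytest.fixture
def mouse_opts():
    return CheckOptions(species="mouse")
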