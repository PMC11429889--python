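import pytest

from phenoforge import build_unified
from phenoforge import fixtures as fx


@pytest.fixture(scope="session")
def supports():
    return fx.fixture_supports()


@pytest.fixture(scope="session")
def templates(supports):
    return fx.fixture_templates(supports)


@pytest.fixture(scope="session")
def filler_tables():
    return fx.fixture_filler_tables()


@pytest.fixture(scope="session")
def species():
    return fx.fixture_species()


@pytest.fixture(scope="session")
def unified(templates, filler_tables, species, supports):
    return build_unified(templates, filler_tables, list(species.values()), supports)


@pytest.fixture(scope="session")
def suite_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_suite")
    fx.make_fixture_suite(out, seed=42)
    return out
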