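import pytest
from hypothesis import HealthCheck, settings

from sumstatfix.fixtures import FixtureSpec, generate_fixture_set
from sumstatfix.io import load_config, load_sumstats

settings.register_profile(
    "default", derandomize=True, max_examples=200,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(n_variants=300, seed=7)


@pytest.fixture(scope="session")
def bundle(spec, tmp_path_factory):
    """VCF + dbSNP index + sumstats + config + chain files, generated once."""
    return generate_fixture_set(spec, tmp_path_factory.mktemp("fixture"),
                                chain_offset=10)


@pytest.fixture(scope="session")
def clean_table(bundle):
    return load_sumstats(bundle["sumstats"], load_config(bundle["config"]))


@pytest.fixture()
def table(clean_table):
    """Function-scoped mutable copy of the clean fixture table."""
    return clean_table.copy()


@pytest.fixture(scope="session")
def index(bundle):
    return bundle["index"]
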