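import pytest

from neurorepo import default_rules, load_curated_fixture


@pytest.fixture(scope="session")
def fixture_kb():
    """Knowledge base built end-to-end from the packaged worked-example bundle."""
    return load_curated_fixture()


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture()
def fresh_kb():
    """A mutable copy for tests that register or delete entities."""
    return load_curated_fixture()
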