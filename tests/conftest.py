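import pytest

from trackmorph.classify import classify_table, default_rules
from trackmorph.io import load_fixture


@pytest.fixture(scope="session")
def fixture_records():
    """The packaged 85-track characterization table."""
    return load_fixture()


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def fixture_audit(fixture_records, rules):
    classifications, audit = classify_table(fixture_records, rules)
    return classifications, audit
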