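import pytest

from peatghg import default_scenarios, harmonize_table, load_reference_table


@pytest.fixture(scope="session")
def reference_records():
    return load_reference_table()


@pytest.fixture(scope="session")
def harmonized(reference_records):
    return harmonize_table(reference_records, mode="paper")


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()
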