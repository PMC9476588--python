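import pytest

from nitrocycle import default_registry, derive_presence, simulate_observed_pattern


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def observed_table():
    return simulate_observed_pattern()


@pytest.fixture(scope="session")
def observed_presence(observed_table):
    return derive_presence(observed_table)
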