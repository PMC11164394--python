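import pytest

from gcsf_cea import default_life_table, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()
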