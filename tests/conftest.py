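import pytest

from bphazard.simulate import load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def panel(table1):
    return table1.compounds()
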