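import pytest

from afscreen import default_costs, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def costs():
    return default_costs()
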