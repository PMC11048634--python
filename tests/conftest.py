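import pytest

import bnburden as bb


@pytest.fixture(scope="session")
def fixture_suite():
    return bb.make_fixture_suite()


@pytest.fixture(scope="session")
def ypn1():
    return bb.make_ypn1_network()


@pytest.fixture(scope="session")
def registry():
    return bb.default_registry()
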