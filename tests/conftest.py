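import pytest

from adlshift.synthetic_data import load_fixture


@pytest.fixture(scope="session")
def michael():
    return load_fixture("michael_f1")


@pytest.fixture(scope="session")
def c1():
    return load_fixture("C1")


@pytest.fixture(scope="session")
def c2():
    return load_fixture("C2")


@pytest.fixture(scope="session")
def c3():
    return load_fixture("C3")


@pytest.fixture(scope="session")
def rho11():
    return load_fixture("rho11")


@pytest.fixture(scope="session")
def rho12():
    return load_fixture("rho12")


@pytest.fixture(scope="session")
def michael_cmap():
    return load_fixture("criticality_map_michael")
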