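import pytest

from pbiopt import fixtures


@pytest.fixture(scope="session")
def imbl_geometry():
    return fixtures.imbl_geometry()


@pytest.fixture(scope="session")
def imbl_table():
    return fixtures.imbl_material_table()


@pytest.fixture(scope="session")
def imbl_model():
    return fixtures.imbl_material_model()


@pytest.fixture(scope="session")
def imbl_sample():
    return fixtures.imbl_sample()
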