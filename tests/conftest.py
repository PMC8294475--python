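import pytest

from ljtypes.chem import build_model
from ljtypes.core import LJParameterSet
from ljtypes.synth import make_library, make_study


@pytest.fixture(scope="session")
def models():
    names = ("HCON", "H2CON", "HC3ON", "HCO3N", "HCON2", "H2CO3N", "H4CON", "H4C3O3N2")
    return {name: build_model(name) for name in names}


@pytest.fixture(scope="session")
def library50():
    return make_library(50, seed=123)


@pytest.fixture(scope="session")
def study40():
    """A small noisy study shared by optimizer/workflow tests."""
    return make_study(n=40, seed=5)


@pytest.fixture()
def hcon_start():
    return LJParameterSet.from_model(build_model("HCON"))
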