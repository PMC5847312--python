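import pytest

from efcm.analysis import EcmCache
from efcm.ecm import Condition
from efcm.efm import enumerate_efms
from efcm.synth import (
    make_branch_tradeoff_model,
    make_chain_model,
    make_diamond_model,
)


@pytest.fixture(scope="session")
def chain_model():
    return make_chain_model(3, seed=1)


@pytest.fixture(scope="session")
def chain_efms(chain_model):
    return enumerate_efms(chain_model)


@pytest.fixture(scope="session")
def diamond_model():
    return make_diamond_model(seed=0)


@pytest.fixture(scope="session")
def branch_model():
    return make_branch_tradeoff_model(seed=0)


@pytest.fixture(scope="session")
def branch_efms(branch_model):
    return enumerate_efms(branch_model)


@pytest.fixture(scope="session")
def reference_condition():
    return Condition()


@pytest.fixture(scope="session")
def shared_cache():
    return EcmCache()
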