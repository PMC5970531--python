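import pytest

from symbionet import network_from_ecs
from symbionet.synthetic_data import (
    bacteriocyte_demo,
    lysine_toy,
    thiamine_toy,
    tryptophan_toy,
)


@pytest.fixture(scope="session")
def demo():
    """The five-genome demo community in the packaged bacteriocyte medium."""
    return bacteriocyte_demo()


@pytest.fixture(scope="session")
def lysine():
    return lysine_toy()


@pytest.fixture(scope="session")
def trp():
    return tryptophan_toy()


@pytest.fixture(scope="session")
def thiamine():
    return thiamine_toy()


def networks_of(fixture):
    return {a.organism_id: network_from_ecs(fixture.universe, a)
            for a in fixture.annotations}
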