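import pytest

from netwin import SimulationConfig
from netwin.fixtures import dominance_demo, load_p53, load_p53_gene_map, toy_network


@pytest.fixture(scope="session")
def toy():
    return toy_network()


@pytest.fixture(scope="session")
def p53():
    return load_p53()


@pytest.fixture(scope="session")
def p53_map():
    return load_p53_gene_map()


@pytest.fixture(scope="session")
def demo():
    """(network, gene map, causal plan) of the designed dominance fixture."""
    return dominance_demo()


@pytest.fixture
def config():
    return SimulationConfig(seed=1)


@pytest.fixture
def dd_on():
    return SimulationConfig(input_clamp={"DNA_damage": 1}, seed=1)


@pytest.fixture
def dd_off():
    return SimulationConfig(input_clamp={"DNA_damage": 0}, seed=1)
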