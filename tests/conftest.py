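import pytest

from evolvex.basis import find_flux_basis
from evolvex.fixtures import toy_network
from evolvex.lp import wild_type_ranges
from evolvex.model import Environment, EvolveXConfig


@pytest.fixture(scope="session")
def toy1():
    return toy_network("TOY1")


@pytest.fixture(scope="session")
def env_a():
    return Environment(frozenset({"EX_A"}), label="A")


@pytest.fixture(scope="session")
def env_b():
    return Environment(frozenset({"EX_B"}), label="B")


@pytest.fixture(scope="session")
def config():
    """The configuration of the worked TOY1 example: tight wild-type
    ranges, growth treated as fitness (excluded from the basis)."""
    return EvolveXConfig(alpha=0.5, delta=0.0, epsilon=1e-6,
                         exclude_from_basis=frozenset({"GROWTH"}))


@pytest.fixture(scope="session")
def wt_a(toy1, env_a, config):
    return wild_type_ranges(toy1, env_a, config)


@pytest.fixture(scope="session")
def basis_a(toy1, env_a, wt_a, config):
    return find_flux_basis(toy1, env_a, "EX_P", wt_a, config)
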