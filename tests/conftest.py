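import numpy as np
import pytest

from rangediv.simulate import SimConfig, generate_clade_dataset, simulate_bd_tree
from rangediv.trees import parse_newick


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tip_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def bd_tree_factory():
    def make(n_tips=20, birth=1.0, death=0.0, seed=0):
        return simulate_bd_tree(n_tips, birth, death, seed=seed)

    return make


@pytest.fixture(scope="session")
def small_clade():
    """One honeyeater-like synthetic clade shared across tests."""
    data, tree = generate_clade_dataset(SimConfig(n_tips=64, seed=2024))
    return data, tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
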