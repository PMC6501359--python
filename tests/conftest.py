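import numpy as np
import pytest

from batlife.trees import Phylogeny
from batlife.simulate import bat_default_config, sim_dataset, sim_tree


@pytest.fixture
def three_tip():
    """((A:1,B:1):1,C:2); — ultrametric, depth 2."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture(scope="session")
def demo_dataset():
    """The shipped 67-species synthetic demo (seed 42)."""
    return sim_dataset(bat_default_config(seed=42))


@pytest.fixture
def random_tree():
    def make(n, seed, scale_height=1.0):
        return sim_tree(n, seed, scale_height=scale_height)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
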