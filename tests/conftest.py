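import numpy as np
import pytest

from fossiltrait.phylo_io import read_newick
from fossiltrait.simulator import simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def cherry():
    """Two extant tips on branches of length 1."""
    return read_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def fossil_tree():
    """3 tips, B is a fossil at age 0.6."""
    return read_newick("((A:1,B:0.4):1,C:2);")


@pytest.fixture
def five_tip():
    return read_newick("(((A:1,B:1):1,(C:1.5,D:1.5):0.5):1,E:3);")


@pytest.fixture
def bd_tree(rng):
    """A ~50-tip birth-death tree with extinct lineages."""
    return simulate_tree(0.25, 0.15, 25, rng, min_fossils=5)
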