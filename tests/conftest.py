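import numpy as np
import pytest

from necomp import parse_newick, simulate_tree
from necomp.phylo import vcv_matrix


@pytest.fixture
def three_taxon_tree():
    """((A:1,B:1):1,C:2); — worked tree with V_AB=1, V_AC=0, diag=2."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def three_taxon_vcv(three_taxon_tree):
    return vcv_matrix(three_taxon_tree)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def yule200():
    """One fixed 200-tip unit-depth Yule tree shared across recovery tests."""
    return simulate_tree(200, 424242)
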