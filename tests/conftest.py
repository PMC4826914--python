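import numpy as np
import pytest

from netsel import trees
from netsel.codons import N_CODONS


@pytest.fixture(scope="session")
def equal_pi():
    return np.full(N_CODONS, 1.0 / N_CODONS)


@pytest.fixture(scope="session")
def five_taxon_tree():
    return trees.default_tree(5, total_length=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160328)


@pytest.fixture(scope="session")
def star3():
    return trees.from_newick("(a:0.2,b:0.1,c:0.3);")
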