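import numpy as np
import pytest

from phylodiv.trees import PhyloTree


@pytest.fixture
def toy_tree():
    """The reference toy phylogeny ((A:1,B:1):1,C:2)."""
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return PhyloTree.from_newick("(A:1,B:1,C:1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
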