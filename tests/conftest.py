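import numpy as np
import pytest

from phyloframe.io_formats import CharacterMatrix
from phyloframe.models import SubstitutionModel
from phyloframe.syndata import (SimulationScenario, simulate_chronogram,
                                simulate_partition)
from phyloframe.trees import Phylotree


@pytest.fixture(scope="session")
def clock_chronogram():
    """10-taxon strict-clock dated tree, root at 50 MY."""
    sc = SimulationScenario(n_taxa=10, clock="strict", base_rate=0.002,
                            root_age=50.0, seed=101)
    return simulate_chronogram(sc)


@pytest.fixture(scope="session")
def clock_tree_subs(clock_chronogram):
    """The same tree with branch lengths in substitutions/site (clock)."""
    t = clock_chronogram.tree.copy()
    for n in t.postorder():
        if n.parent is not None:
            n.length = (n.parent.annotations["age"]
                        - n.annotations["age"]) * 0.002
    return t


@pytest.fixture(scope="session")
def six_taxon_chronogram():
    sc = SimulationScenario(n_taxa=6, clock="strict", base_rate=0.01,
                            root_age=10.0, seed=7)
    return simulate_chronogram(sc)


@pytest.fixture(scope="session")
def six_taxon_jc_data(six_taxon_chronogram):
    return simulate_partition(six_taxon_chronogram, SubstitutionModel.jc(),
                              3000, seed=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def quartet_tree():
    return Phylotree.from_newick(
        "((a:0.1,b:0.2):0.15,(c:0.3,d:0.05):0.2);").unroot()


@pytest.fixture()
def quartet_matrix():
    return CharacterMatrix(["a", "b", "c", "d"], ["ACG?", "AAGT", "CAGT", "CCG-"])
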