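import numpy as np
import pytest

from phryno import mk, simulate
from phryno.tree import tree_from_newick


@pytest.fixture(scope="session")
def cherry():
    return tree_from_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def three_tip():
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def star_tree():
    """Equal-branch star phylogeny: phylogenetic methods must reduce to
    their ordinary (iid) counterparts here."""
    n = 40
    return tree_from_newick("(" + ",".join(f"t{i}:1" for i in range(n)) + ");")


@pytest.fixture(scope="session")
def midsize_tree():
    return simulate.simulate_tree(80, 0.08, 0.03, seed=11, height=65.0)


@pytest.fixture(scope="session")
def study():
    """A full synthetic study dataset at the emulated empirical scale."""
    return simulate.generate_study_dataset(simulate.SynthConfig(seed=7, n_tips=125))


@pytest.fixture(scope="session")
def study_maps(study):
    """A modest set of stochastic parity maps on the study tree."""
    fit = mk.fit_mk(study.tree, study.parity(), "ER")
    return mk.stochastic_maps(study.tree, study.parity(), fit, 25, seed=19)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
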