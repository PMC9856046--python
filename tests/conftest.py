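import numpy as np
import pytest

from pollencrp.grammar import load_class_definitions
from pollencrp.selection import equal_codon_freqs
from pollencrp.simulate import random_tree, sim_codon_alignment


@pytest.fixture(scope="session")
def class_defs():
    return load_class_definitions()


@pytest.fixture(scope="session")
def uniform_freqs():
    return equal_codon_freqs()


@pytest.fixture(scope="session")
def small_tree():
    """4-taxon tree, small enough for the brute-force likelihood oracle."""
    return random_tree(4, seed=7, mean_branch=0.15)


@pytest.fixture(scope="session")
def small_alignment(small_tree, uniform_freqs):
    aln, _ = sim_codon_alignment(
        small_tree, kappa=2.0, omegas=[0.5], class_weights=[1.0],
        freqs=uniform_freqs, n_sites=20, seed=11,
    )
    return aln


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
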