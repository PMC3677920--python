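import numpy as np
import pytest

import phylocoev as pc


@pytest.fixture
def three_taxon_tree():
    return pc.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def fixture_dataset():
    return pc.make_study_like_fixture(seed=0)


def random_tree(rng, n=None, birth_rate=1.0):
    n = n or int(rng.integers(4, 9))
    return pc.simulate_yule_tree(n, birth_rate, rng)


def random_generator_matrix(rng, k):
    Q = rng.uniform(0.1, 2.0, (k, k))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def random_character(rng, tree, k, labels=None):
    space = labels or [f"s{i}" for i in range(k)]
    return pc.CharacterData(
        list(space),
        {lab: int(rng.integers(k)) for lab in sorted(tree.taxa)})
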