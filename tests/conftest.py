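import numpy as np
import pytest

from asrbench import (
    IndelParams,
    RateModel,
    TreeSimParams,
    evolve,
    read_newick,
    simulate_tree,
)


@pytest.fixture(scope="session")
def wag_model():
    return RateModel(gamma_shape=1.8, n_categories=4)


@pytest.fixture(scope="session")
def wag_model_k2():
    return RateModel(gamma_shape=1.8, n_categories=2)


@pytest.fixture
def quartet():
    return read_newick("((A:0.3,B:0.7)N2:0.25,(C:0.5,D:0.9)N3:0.15)N1;")


@pytest.fixture(scope="session")
def small_history(wag_model):
    """One seeded 8-taxon replicate with indels, reused across read-only tests."""
    tree = simulate_tree(TreeSimParams(n_taxa=8, height=1.0, sampling_fraction=0.5, seed=42))
    return evolve(tree, wag_model, IndelParams(0.05, 0.05), root_length=120, seed=43)
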