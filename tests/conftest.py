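import numpy as np
import pytest

import absfit as af


@pytest.fixture
def tiny_msa():
    """Three 2-column sequences whose pair counts are known by hand."""
    return af.msa_from_sequences([("t1", "AC"), ("t2", "AG"), ("t3", "CG")])


@pytest.fixture
def fig1_trees():
    """Six-taxon tree pair: A sister to B vs A sister to C, otherwise identical."""
    t1 = af.tree_from_newick("(((A,B),C),((D,E),F));", label="TreeI")
    t2 = af.tree_from_newick("(((A,C),B),((D,E),F));", label="TreeII")
    return t1, t2


def random_msa(rng: np.random.Generator, n: int = 5, k: int = 20) -> af.Msa:
    codes = rng.integers(0, 4, size=(n, k)).astype(np.uint8)
    return af.Msa(taxa=tuple(f"t{i}" for i in range(n)), codes=codes)


@pytest.fixture(scope="session")
def reduced_power_study():
    """The two-tree power study at its default scale (k=10,000, 20 observed
    replicates, q=100 per candidate), shared by the model-separation and
    Goldman-Cox contrast checks."""
    from absfit.workflows import power_study

    return power_study(seed=2024)
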