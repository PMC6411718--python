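import numpy as np
import pytest

from sensetrade import Phylogeny, read_newick, simulate_tree


@pytest.fixture(scope="session")
def cherry() -> Phylogeny:
    return read_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def three_tip() -> Phylogeny:
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def star_tree() -> Phylogeny:
    """16 tips all attached to the root with unit branches: V = identity."""
    tips = ",".join(f"t{i:02d}:1" for i in range(16))
    return read_newick(f"({tips});")


@pytest.fixture(scope="session")
def two_clade_tree() -> Phylogeny:
    """Two deep clades of 5 shallow tips each."""
    left = "(" + ",".join(f"a{i}:0.1" for i in range(5)) + "):0.9"
    right = "(" + ",".join(f"b{i}:0.1" for i in range(5)) + "):0.9"
    return read_newick(f"({left},{right});")


@pytest.fixture(scope="session")
def yule20() -> Phylogeny:
    return simulate_tree(20, seed=20)


@pytest.fixture(scope="session")
def yule59() -> Phylogeny:
    return simulate_tree(59, seed=59)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
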