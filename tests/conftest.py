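import numpy as np
import pytest

from braingtd.ontology import BrainCounts, OntologyTree, Region
from braingtd.synthetic import build_toy_ontology


@pytest.fixture
def chain_tree():
    """Three regions in a chain: 1 -> 2 -> 3."""
    return OntologyTree(
        {
            1: Region(1, "A", "region A", None),
            2: Region(2, "B", "region B", 1),
            3: Region(3, "C", "region C", 2),
        }
    )


@pytest.fixture
def flat_tree():
    """Root with two leaf children (ids 1; 2, 3)."""
    return build_toy_ontology(1, 2)


@pytest.fixture
def toy_tree():
    """Complete depth-2, branching-3 tree (13 regions, 9 leaves)."""
    return build_toy_ontology(2, 3)


def random_tree(rng: np.random.Generator, max_regions: int = 20):
    """A random rooted tree: node i's parent is drawn among nodes < i."""
    n = int(rng.integers(2, max_regions + 1))
    parents = {1: None}
    for i in range(2, n + 1):
        parents[i] = int(rng.integers(1, i))
    regions = {
        i: Region(i, f"A{i}", f"region {i}", parents[i]) for i in parents
    }
    return OntologyTree(regions), parents


def random_brain(
    rng: np.random.Generator,
    tree: OntologyTree,
    brain_id: str,
    max_count: int = 50,
) -> BrainCounts:
    direct = {
        rid: int(rng.integers(0, max_count + 1)) for rid in tree.regions
    }
    if sum(direct.values()) == 0:
        direct[tree.root_id] = 1
    return BrainCounts.from_direct(brain_id, direct, tree)
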