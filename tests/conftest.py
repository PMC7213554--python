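import pytest

from occutree.fixtures import (
    FixtureSpec,
    make_backbone,
    make_landscape,
    tutorial_landscape,
)
from occutree.grid import GridSpec
from occutree.tree import Tree


@pytest.fixture(scope="session")
def tutorial():
    """(grid, backbone, t1 occurrences, t2 occurrences) worked-example preset."""
    return tutorial_landscape(seed=0)


@pytest.fixture(scope="session")
def t1_tree(tutorial):
    grid, backbone, t1, _ = tutorial
    return Tree(t1, backbone)


@pytest.fixture(scope="session")
def t2_tree(tutorial):
    grid, backbone, _, t2 = tutorial
    return Tree(t2, backbone)


@pytest.fixture(scope="session")
def chain_backbone():
    """Minimal single-lineage backbone: one node per rank, root to species."""
    return make_backbone((1, 1, 1, 1, 1, 1, 1))


@pytest.fixture()
def small_landscape():
    """A small random landscape shared by graph/pipeline tests."""
    spec = FixtureSpec(
        seed=11, n_occurrences=300, grid=GridSpec(0.0, 0.0, 1.0, 1.0, 0.1)
    )
    return make_landscape(spec)


def brute_force_lineage_tally(occurrences, backbone):
    """Independent per-taxon occurrence tally: walk every record's lineage."""
    tally: dict[int, int] = {}
    for occ in occurrences:
        for node in backbone.lineage_of(occ.species_id):
            tally[node.id] = tally.get(node.id, 0) + 1
    return tally
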