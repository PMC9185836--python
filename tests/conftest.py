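"""Shared fixtures: the worked six-leaf examples and random generators."""

import random

import pytest

from brauerphylo import (
    PartitionDiagram,
    SandwichContext,
    SetPartition,
    make_partition_diagram,
    parse_newick,
)

# The six-leaf tree whose matching is {{1,10},{2,3},{4,6},{5,7},{8,9}}.
SIX_LEAF_NEWICK = "(1,((4,6),(5,(2,3))));"
SIX_LEAF_MATCHING = [[1, 10], [2, 3], [4, 6], [5, 7], [8, 9]]

# The rank-4 (caterpillar) context tree of the worked regularity example.
CATERPILLAR_MATCHING = [[1, 10], [2, 9], [3, 4], [5, 8], [6, 7]]

# Partition on 13 points whose forest has components {5}, a tree rooted at
# the labelled vertex 11 over leaves {1,3,4,6}, and a tree over {2,7,8,9}.
FOREST_PARTITION_13 = [[1, 10], [3, 4, 6], [5], [7, 8], [9, 13], [2, 12], [11]]

# Partition of 12 points giving a nine-leaf tree with three internal
# non-root vertices.
NONBINARY_PARTITION_12 = [[1, 3, 12], [2, 9], [4, 6, 8, 11], [5, 7, 10]]


@pytest.fixture
def six_leaf_forest():
    return parse_newick(SIX_LEAF_NEWICK)


@pytest.fixture
def six_leaf_diagram() -> PartitionDiagram:
    return make_partition_diagram(6, 4, SIX_LEAF_MATCHING)


@pytest.fixture
def caterpillar_ctx() -> SandwichContext:
    return SandwichContext.from_matching(6, CATERPILLAR_MATCHING)


@pytest.fixture
def rank0_ctx() -> SandwichContext:
    return SandwichContext.from_matching(
        6, [[1, 2], [3, 4], [5, 6], [7, 8], [9, 10]]
    )


def random_set_partition(rng: random.Random, t: int) -> SetPartition:
    """A random (not uniform) set partition of {1..t}."""
    blocks: list[list[int]] = []
    for x in range(1, t + 1):
        if blocks and rng.random() < 0.6:
            rng.choice(blocks).append(x)
        else:
            blocks.append([x])
    return SetPartition(t, blocks)


def random_diagram(rng: random.Random, n: int, m: int) -> PartitionDiagram:
    return PartitionDiagram(n, m, random_set_partition(rng, n + m))


def random_matching_diagram(rng: random.Random, n: int, m: int) -> PartitionDiagram:
    """A random Brauer diagram on an (n, m) frame (n + m even)."""
    pool = list(range(1, n + m + 1))
    pairs = []
    while pool:
        first = pool.pop(0)
        pairs.append([first, pool.pop(rng.randrange(len(pool)))])
    return make_partition_diagram(n, m, pairs)
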