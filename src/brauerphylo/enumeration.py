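"""Exhaustive and random generation of partitions, matchings, trees, forests.

Everything here is label-explicit: binary trees on n leaves are reached
through the (2n-3)!! perfect matchings of [2n-2], general trees through the
no-singleton set partitions with |pi| - l(pi) + 1 = n, and forests through
arbitrary partitions with |pi| - l_{>=2}(pi) + 1 = n (plus the trivial
partition of [n] for the trivial forest).

Set partitions are iterated canonically by assigning the smallest unplaced
element either to an existing block or to a fresh one, so the order is
deterministic and duplicate-free.  Counts of partitions with restricted
block sizes come from the partial-Bell recursion
f(t) = sum_s C(t-1, s-1) f(t-s) over allowed sizes s (the block of the
smallest element has size s).
"""

from __future__ import annotations

import math
import random
from functools import lru_cache
from typing import Callable, Iterable, Iterator

from .bijections import partition_to_forest
from .diagram_core import PartitionDiagram, SetPartition
from .errors import ValidationError
from .trees_forests import Forest

__all__ = [
    "all_set_partitions",
    "all_matchings",
    "all_brauer_diagrams",
    "count_restricted_partitions",
    "all_phylo",
    "count_by_rank",
    "random_phylo",
]

ENUMERATION_GUARD = 10


def _guard(n: int, force: bool) -> None:
    if n > ENUMERATION_GUARD and not force:
        raise ValidationError(
            f"enumeration refused for n={n} > {ENUMERATION_GUARD}; "
            "pass force=True to override"
        )


# ---------------------------------------------------------------------------
# set partitions


def all_set_partitions(
    t: int, size_filter: Callable[[int], bool] | None = None
) -> Iterator[SetPartition]:
    """All set partitions of {1..t}, canonically ordered, optionally filtered.

    ``size_filter`` is a predicate on block sizes; a partition is yielded
    only if every block size satisfies it.
    """
    if t < 1:
        raise ValidationError("ground size must be >= 1")

    def recurse(element: int, blocks: list[list[int]]) -> Iterator[list[list[int]]]:
        if element > t:
            yield blocks
            return
        for block in blocks:
            block.append(element)
            yield from recurse(element + 1, blocks)
            block.pop()
        blocks.append([element])
        yield from recurse(element + 1, blocks)
        blocks.pop()

    for blocks in recurse(1, []):
        if size_filter is None or all(size_filter(len(b)) for b in blocks):
            yield SetPartition(t, [list(b) for b in blocks])


def all_matchings(t: int) -> Iterator[SetPartition]:
    """All perfect matchings of {1..t} (t even), canonically ordered."""
    if t < 2 or t % 2:
        raise ValidationError(f"perfect matchings need an even ground size, got {t}")

    def recurse(remaining: tuple[int, ...]) -> Iterator[list[tuple[int, int]]]:
        if not remaining:
            yield []
            return
        first, rest = remaining[0], remaining[1:]
        for idx, partner in enumerate(rest):
            sub = rest[:idx] + rest[idx + 1 :]
            for tail in recurse(sub):
                yield [(first, partner)] + tail

    for pairs in recurse(tuple(range(1, t + 1))):
        yield SetPartition(t, [list(p) for p in pairs])


def all_brauer_diagrams(n: int) -> Iterator[PartitionDiagram]:
    """All of B_{n,n-2}: matchings of [2n-2] on an (n, n-2) frame."""
    for matching in all_matchings(2 * n - 2):
        yield PartitionDiagram(n, n - 2, matching)


def count_restricted_partitions(t: int, allowed_sizes: Iterable[int]) -> int:
    """Number of set partitions of [t] with every block size in the set.

    Uses the recursion over the block containing the smallest element.
    """
    if t < 1:
        raise ValidationError("ground size must be >= 1")
    sizes = sorted({s for s in allowed_sizes if 1 <= s <= t})
    f = [0] * (t + 1)
    f[0] = 1
    for u in range(1, t + 1):
        f[u] = sum(math.comb(u - 1, s - 1) * f[u - s] for s in sizes if s <= u)
    return f[t]


# number of partitions of [t] into exactly l blocks, all of size >= 2
# (2-associated Stirling numbers of the second kind)
@lru_cache(maxsize=None)
def _assoc_stirling2(t: int, blocks: int) -> int:
    if t == 0:
        return 1 if blocks == 0 else 0
    if blocks <= 0 or t < 2 * blocks:
        return 0
    return blocks * _assoc_stirling2(t - 1, blocks) + (t - 1) * _assoc_stirling2(
        t - 2, blocks - 1
    )


# ---------------------------------------------------------------------------
# phylogenetic enumeration


def all_phylo(n: int, mode: str, force: bool = False) -> Iterator[Forest]:
    """Every binary tree / tree / forest on leaves 1..n, each exactly once.

    binary_trees: via the (2n-3)!! perfect matchings of [2n-2].
    trees: via no-singleton partitions with |pi| - l(pi) + 1 = n.
    forests: via all partitions with |pi| - l_{>=2}(pi) + 1 = n, preceded by
    the trivial forest.
    """
    _guard(n, force)
    if mode == "binary_trees":
        if n < 2:
            raise ValidationError("binary trees need n >= 2")
        for matching in all_matchings(2 * n - 2):
            yield partition_to_forest(matching)
    elif mode == "trees":
        if n < 2:
            raise ValidationError("trees need n >= 2")
        for n_blocks in range(1, n):
            t = n + n_blocks - 1
            for pi in all_set_partitions(t, lambda s: s >= 2):
                if pi.n_blocks == n_blocks:
                    yield partition_to_forest(pi)
    elif mode == "forests":
        if n < 1:
            raise ValidationError("forests need n >= 1")
        yield partition_to_forest(SetPartition(n, [[i] for i in range(1, n + 1)]))
        for nontrivial in range(1, n):
            t = n + nontrivial - 1
            for pi in all_set_partitions(t):
                if pi.n_nontrivial == nontrivial:
                    yield partition_to_forest(pi)
    else:
        raise ValidationError(f"unknown mode {mode!r}")


def count_by_rank(n: int, force: bool = False) -> dict[int, int]:
    """Rank census of all binary-tree diagrams in B_{n,n-2}."""
    from .diagram_core import analyze

    _guard(n, force)
    census: dict[int, int] = {}
    for alpha in all_brauer_diagrams(n):
        k = analyze(alpha).rank
        census[k] = census.get(k, 0) + 1
    return dict(sorted(census.items()))


# ---------------------------------------------------------------------------
# random generation


def _uniform_matching(t: int, rng: random.Random) -> SetPartition:
    pool = list(range(1, t + 1))
    pairs = []
    while pool:
        first = pool.pop(0)
        partner = pool.pop(rng.randrange(len(pool)))
        pairs.append([first, partner])
    return SetPartition(t, pairs)


def _sample_no_singleton(
    elements: list[int], blocks: int, rng: random.Random
) -> list[list[int]]:
    """Uniform partition of ``elements`` into ``blocks`` blocks, all >= 2.

    Follows the recursion b(t,l) = l b(t-1,l) + (t-1) b(t-2,l-1): the last
    element either joins one of the l blocks of a partition of the rest, or
    pairs with one chosen element to found a block.
    """
    t = len(elements)
    if blocks == 0:
        return []
    total = _assoc_stirling2(t, blocks)
    stay = blocks * _assoc_stirling2(t - 1, blocks)
    last = elements[-1]
    if rng.randrange(total) < stay:
        part = _sample_no_singleton(elements[:-1], blocks, rng)
        part[rng.randrange(blocks)].append(last)
        return part
    mate_idx = rng.randrange(t - 1)
    rest = elements[:-1]
    mate = rest.pop(mate_idx)
    part = _sample_no_singleton(rest, blocks - 1, rng)
    part.append([mate, last])
    return part


def random_phylo(
    n: int, seed: int | random.Random, mode: str = "binary"
) -> Forest:
    """A uniformly random rooted tree on leaves 1..n, as a one-tree forest.

    binary: a uniform perfect matching of [2n-2]; the matching-tree
    bijection makes every matching a tree and the draw uniform over the
    (2n-3)!! labelled topologies.

    general: uniform over all rooted phylogenetic trees on n leaves, drawn
    by first picking the number of non-leaf vertices proportionally to the
    number of eligible no-singleton partitions, then sampling such a
    partition uniformly.
    """
    if n < 2:
        raise ValidationError("random trees need n >= 2")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    if mode == "binary":
        return partition_to_forest(_uniform_matching(2 * n - 2, rng))
    if mode == "general":
        weights = {
            blocks: _assoc_stirling2(n + blocks - 1, blocks)
            for blocks in range(1, n)
        }
        total = sum(weights.values())
        pick = rng.randrange(total)
        for blocks, w in weights.items():
            if pick < w:
                break
            pick -= w
        t = n + blocks - 1
        part = _sample_no_singleton(list(range(1, t + 1)), blocks, rng)
        return partition_to_forest(SetPartition(t, part))
    raise ValidationError(f"unknown mode {mode!r}")
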