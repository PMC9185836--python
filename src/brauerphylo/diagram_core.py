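"""Set partitions, partition/Brauer diagrams, and their algebra.

A *partition diagram* lays a set partition of {1..n+m} out on two rows:
``n`` top nodes labelled 1..n left-to-right and ``m`` bottom nodes labelled
n+1..n+m placed **right-to-left**, so the numbering continues clockwise
around the frame.  Under this convention the bottom node at left-to-right
position ``p`` (1-based) carries label ``n + m + 1 - p``.

A *Brauer diagram* is the special case in which every block has exactly two
elements (a perfect matching).

Composition of an (n, m) diagram above an (m, k) diagram glues the m bottom
nodes of the upper diagram to the m top nodes of the lower diagram **by
left-to-right position**, merges blocks across the interface, deletes any
component living entirely in the glued middle row, and reports the number of
such deleted components (the loops; with loop parameter fixed at 1 they
carry no further weight).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator

from .errors import DimensionMismatchError, ValidationError

__all__ = [
    "SetPartition",
    "PartitionDiagram",
    "DiagramStats",
    "Equivalence",
    "make_partition_diagram",
    "compose",
    "flip",
    "analyze",
    "join_equivalences",
    "separates",
    "diagram_to_text",
    "diagram_from_text",
    "diagram_to_json",
    "diagram_from_json",
]


def _canonical_blocks(blocks: Iterable[Iterable[int]]) -> tuple[tuple[int, ...], ...]:
    """Sort each block ascending, then sort blocks by minimum element."""
    return tuple(sorted((tuple(sorted(b)) for b in blocks), key=lambda b: b[:1]))


class SetPartition:
    """A set partition of the ground set {1..t}.

    Blocks are stored canonically: each block sorted ascending, blocks
    ordered by their minimum element.  Equality and hashing follow the
    canonical form.
    """

    __slots__ = ("ground_size", "blocks")

    def __init__(self, ground_size: int, blocks: Iterable[Iterable[int]]):
        if ground_size < 1:
            raise ValidationError(f"ground size must be >= 1, got {ground_size}")
        canon = _canonical_blocks(blocks)
        seen: set[int] = set()
        for block in canon:
            if not block:
                raise ValidationError("empty block in set partition")
            for x in block:
                if not isinstance(x, int) or x < 1 or x > ground_size:
                    raise ValidationError(
                        f"label {x!r} outside ground set 1..{ground_size}"
                    )
                if x in seen:
                    raise ValidationError(f"label {x} appears in more than one block")
                seen.add(x)
        if len(seen) != ground_size:
            missing = sorted(set(range(1, ground_size + 1)) - seen)
            raise ValidationError(f"labels {missing} not covered by any block")
        object.__setattr__(self, "ground_size", ground_size)
        object.__setattr__(self, "blocks", canon)

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("SetPartition is immutable")

    # -- accessors ---------------------------------------------------------
    @property
    def size(self) -> int:
        """|pi|: size of the ground set."""
        return self.ground_size

    @property
    def n_blocks(self) -> int:
        """l(pi): number of blocks."""
        return len(self.blocks)

    @property
    def n_nontrivial(self) -> int:
        """l_{>=2}(pi): number of blocks of size at least 2."""
        return sum(1 for b in self.blocks if len(b) >= 2)

    @property
    def singletons(self) -> tuple[int, ...]:
        return tuple(b[0] for b in self.blocks if len(b) == 1)

    @property
    def is_trivial(self) -> bool:
        """True if every block is a singleton."""
        return self.n_nontrivial == 0

    @property
    def is_matching(self) -> bool:
        """True if every block has exactly two elements."""
        return all(len(b) == 2 for b in self.blocks)

    def block_of(self, x: int) -> tuple[int, ...]:
        for b in self.blocks:
            if x in b:
                return b
        raise KeyError(x)

    def relabel(self, mapping: Callable[[int], int], ground_size: int | None = None) -> "SetPartition":
        """Apply a label bijection and return the resulting partition."""
        size = self.ground_size if ground_size is None else ground_size
        return SetPartition(size, [[mapping(x) for x in b] for b in self.blocks])

    # -- dunder ------------------------------------------------------------
    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SetPartition)
            and self.ground_size == other.ground_size
            and self.blocks == other.blocks
        )

    def __hash__(self) -> int:
        return hash((self.ground_size, self.blocks))

    def __iter__(self) -> Iterator[tuple[int, ...]]:
        return iter(self.blocks)

    def __repr__(self) -> str:
        inner = "|".join(",".join(map(str, b)) for b in self.blocks)
        return f"SetPartition({self.ground_size}, {inner})"


class PartitionDiagram:
    """A set partition of {1..n+m} laid out on n top + m bottom nodes."""

    __slots__ = ("n_top", "m_bottom", "partition")

    def __init__(self, n_top: int, m_bottom: int, partition: SetPartition):
        # n_top = 0 arises only as the flip of a bottomless diagram
        if n_top < 0 or m_bottom < 0 or n_top + m_bottom < 1:
            raise ValidationError(
                f"need n_top, m_bottom >= 0 with at least one node, "
                f"got ({n_top}, {m_bottom})"
            )
        if partition.ground_size != n_top + m_bottom:
            raise ValidationError(
                f"partition covers 1..{partition.ground_size}, expected "
                f"1..{n_top + m_bottom} for an ({n_top}, {m_bottom}) diagram"
            )
        object.__setattr__(self, "n_top", n_top)
        object.__setattr__(self, "m_bottom", m_bottom)
        object.__setattr__(self, "partition", partition)

    def __setattr__(self, name, value):
        raise AttributeError("PartitionDiagram is immutable")

    # -- layout helpers ----------------------------------------------------
    def is_top(self, label: int) -> bool:
        return 1 <= label <= self.n_top

    def bottom_label(self, position: int) -> int:
        """Label of the bottom node at left-to-right position p (1-based)."""
        if not 1 <= position <= self.m_bottom:
            raise ValidationError(f"bottom position {position} out of range")
        return self.n_top + self.m_bottom + 1 - position

    def bottom_position(self, label: int) -> int:
        """Left-to-right position (1-based) of a bottom label."""
        if not self.n_top < label <= self.n_top + self.m_bottom:
            raise ValidationError(f"{label} is not a bottom label")
        return self.n_top + self.m_bottom + 1 - label

    @property
    def is_brauer(self) -> bool:
        return self.partition.is_matching

    @property
    def blocks(self) -> tuple[tuple[int, ...], ...]:
        return self.partition.blocks

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PartitionDiagram)
            and self.n_top == other.n_top
            and self.m_bottom == other.m_bottom
            and self.partition == other.partition
        )

    def __hash__(self) -> int:
        return hash((self.n_top, self.m_bottom, self.partition))

    def __repr__(self) -> str:
        return f"PartitionDiagram({diagram_to_text(self)!r})"


@dataclass(frozen=True)
class DiagramStats:
    """dom/codom/ker/coker/rank analytics of a diagram.

    ``ker`` and ``coker`` are symmetric relations stored as frozensets of
    ordered pairs, containing both (i, j) and (j, i) for distinct same-row
    labels sharing a block.  ``u_ker`` / ``u_coker`` are their underlying
    sets.
    """

    dom: frozenset[int]
    codom: frozenset[int]
    ker: frozenset[tuple[int, int]]
    coker: frozenset[tuple[int, int]]
    rank: int

    @property
    def u_ker(self) -> frozenset[int]:
        return frozenset(i for i, _ in self.ker)

    @property
    def u_coker(self) -> frozenset[int]:
        return frozenset(i for i, _ in self.coker)

    def ker_classes(self) -> frozenset[frozenset[int]]:
        """ker as a collection of same-block top classes (size >= 2)."""
        return _pairs_to_classes(self.ker)

    def coker_classes(self) -> frozenset[frozenset[int]]:
        return _pairs_to_classes(self.coker)


def _pairs_to_classes(pairs: frozenset[tuple[int, int]]) -> frozenset[frozenset[int]]:
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in pairs:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, set[int]] = {}
    for x in parent:
        groups.setdefault(find(x), set()).add(x)
    return frozenset(frozenset(g) for g in groups.values())


class Equivalence:
    """An equivalence relation on a finite ground set.

    Stored as the partition into classes, with unrelated points kept as
    singleton classes (so the relation is reflexive by construction).
    """

    __slots__ = ("ground", "classes")

    def __init__(self, ground: Iterable[int], classes: Iterable[Iterable[int]] = ()):
        ground_set = frozenset(ground)
        parent = {x: x for x in ground_set}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for cls in classes:
            cls = list(cls)
            for x in cls:
                if x not in ground_set:
                    raise ValidationError(f"{x} not in ground set")
            for a, b in zip(cls, cls[1:]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        groups: dict[int, set[int]] = {}
        for x in ground_set:
            groups.setdefault(find(x), set()).add(x)
        object.__setattr__(self, "ground", ground_set)
        object.__setattr__(
            self, "classes", frozenset(frozenset(g) for g in groups.values())
        )

    def __setattr__(self, name, value):
        raise AttributeError("Equivalence is immutable")

    @classmethod
    def from_pairs(cls, ground: Iterable[int], pairs: Iterable[tuple[int, int]]) -> "Equivalence":
        return cls(ground, ([a, b] for a, b in pairs))

    def related(self, a: int, b: int) -> bool:
        return any(a in c and b in c for c in self.classes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Equivalence)
            and self.ground == other.ground
            and self.classes == other.classes
        )

    def __hash__(self) -> int:
        return hash((self.ground, self.classes))

    def __repr__(self) -> str:
        parts = sorted(sorted(c) for c in self.classes)
        return f"Equivalence({parts})"


# ---------------------------------------------------------------------------
# operations


def make_partition_diagram(
    n: int, m: int, blocks: Iterable[Iterable[int]]
) -> PartitionDiagram:
    """Build the (n, m) diagram of a set partition of {1..n+m}."""
    return PartitionDiagram(n, m, SetPartition(n + m, blocks))


def compose(
    upper: PartitionDiagram, lower: PartitionDiagram
) -> tuple[PartitionDiagram, int]:
    """Concatenate ``upper`` above ``lower`` and merge across the interface.

    Returns ``(diagram, loops_removed)`` where the diagram is the (n, k)
    result and ``loops_removed`` counts deleted middle-only components.

    Raises
    ------
    DimensionMismatchError
        If ``upper.m_bottom != lower.n_top`` (the categorical product of an
        (n, m) with an (m', k) diagram exists only when m == m').
    """
    m = upper.m_bottom
    if m != lower.n_top:
        raise DimensionMismatchError(
            f"cannot compose ({upper.n_top},{upper.m_bottom}) with "
            f"({lower.n_top},{lower.m_bottom}) diagram: inner dimensions "
            f"{upper.m_bottom} != {lower.n_top}"
        )
    n = upper.n_top
    k = lower.m_bottom

    # Node universe: ('t', i) result top labels, ('mid', p) glued middle
    # positions 1..m, ('b', j) result bottom labels.  The gluing is by
    # left-to-right position: the upper diagram's bottom node at position p
    # meets the lower diagram's top node at position p.
    parent: dict = {}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(a, b):
        if a not in parent:
            parent[a] = a
        if b not in parent:
            parent[b] = b
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    def upper_node(label: int):
        if upper.is_top(label):
            return ("t", label)
        return ("mid", upper.bottom_position(label))

    def lower_node(label: int):
        if lower.is_top(label):
            return ("mid", label)  # lower top positions coincide with labels
        # lower bottom label j -> result bottom label j - m + n
        return ("b", label - m + n)

    for i in range(1, n + 1):
        union(("t", i), ("t", i))
    for p in range(1, m + 1):
        union(("mid", p), ("mid", p))
    for j in range(n + 1, n + k + 1):
        union(("b", j), ("b", j))
    for block in upper.blocks:
        nodes = [upper_node(x) for x in block]
        for a, b in zip(nodes, nodes[1:]):
            union(a, b)
    for block in lower.blocks:
        nodes = [lower_node(x) for x in block]
        for a, b in zip(nodes, nodes[1:]):
            union(a, b)

    components: dict = {}
    for node in parent:
        components.setdefault(find(node), []).append(node)

    blocks: list[list[int]] = []
    loops = 0
    for nodes in components.values():
        labels = [lab for kind, lab in nodes if kind in ("t", "b")]
        if labels:
            blocks.append(labels)
        else:
            loops += 1
    return PartitionDiagram(n, k, SetPartition(n + k, blocks)), loops


def flip(alpha: PartitionDiagram) -> PartitionDiagram:
    """Reflect a diagram about the horizontal axis.

    The node at top position i swaps with the node at bottom position i.
    Under the clockwise labelling this is the label map x -> n + m + 1 - x
    on an (m, n) frame, so ``flip(flip(alpha)) == alpha`` and the balanced
    diagram of a matching is flip-symmetric exactly when its block set is
    stable under that map.
    """
    total = alpha.n_top + alpha.m_bottom
    part = alpha.partition.relabel(lambda x: total + 1 - x)
    return PartitionDiagram(alpha.m_bottom, alpha.n_top, part)


def analyze(alpha: PartitionDiagram) -> DiagramStats:
    """Compute dom, codom, ker, coker and rank of a diagram.

    A transversal block meets both rows; dom/codom collect its top/bottom
    labels and rank counts such blocks.  ker (resp. coker) holds both
    ordered pairs for every two distinct top (resp. bottom) labels sharing
    a block.
    """
    dom: set[int] = set()
    codom: set[int] = set()
    ker: set[tuple[int, int]] = set()
    coker: set[tuple[int, int]] = set()
    rank = 0
    for block in alpha.blocks:
        tops = [x for x in block if alpha.is_top(x)]
        bots = [x for x in block if not alpha.is_top(x)]
        if tops and bots:
            rank += 1
            dom.update(tops)
            codom.update(bots)
        for row, rel in ((tops, ker), (bots, coker)):
            for a in row:
                for b in row:
                    if a != b:
                        rel.add((a, b))
    return DiagramStats(
        dom=frozenset(dom),
        codom=frozenset(codom),
        ker=frozenset(ker),
        coker=frozenset(coker),
        rank=rank,
    )


def join_equivalences(r1: Equivalence, r2: Equivalence) -> Equivalence:
    """Smallest equivalence containing both (join in the lattice)."""
    if r1.ground != r2.ground:
        raise ValidationError("equivalences defined on different ground sets")
    return Equivalence(r1.ground, list(r1.classes) + list(r2.classes))


def separates(eq: Equivalence, targets: Iterable[int]) -> bool:
    """True iff every class of ``eq`` contains at most one target point."""
    targets = set(targets)
    if not targets <= eq.ground:
        raise ValidationError("targets must lie in the ground set")
    return all(len(cls & targets) <= 1 for cls in eq.classes)


# ---------------------------------------------------------------------------
# serialization: text dialect  n=6;m=4;blocks=1,10|2,3|4,6|5,7|8,9


def diagram_to_text(alpha: PartitionDiagram) -> str:
    inner = "|".join(",".join(map(str, b)) for b in alpha.blocks)
    return f"n={alpha.n_top};m={alpha.m_bottom};blocks={inner}"


def diagram_from_text(text: str) -> PartitionDiagram:
    try:
        fields = dict(item.split("=", 1) for item in text.strip().split(";"))
        n = int(fields["n"])
        m = int(fields["m"])
        blocks = [
            [int(x) for x in chunk.split(",")]
            for chunk in fields["blocks"].split("|")
            if chunk
        ]
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"cannot parse diagram text {text!r}: {exc}") from exc
    return make_partition_diagram(n, m, blocks)


def diagram_to_json(alpha: PartitionDiagram) -> str:
    return json.dumps(
        {
            "n": alpha.n_top,
            "m": alpha.m_bottom,
            "blocks": [list(b) for b in alpha.blocks],
        }
    )


def diagram_from_json(text: str) -> PartitionDiagram:
    try:
        data = json.loads(text)
        return make_partition_diagram(data["n"], data["m"], data["blocks"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"cannot parse diagram JSON: {exc}") from exc
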