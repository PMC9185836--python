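"""Correspondences between forests, set partitions and diagrams.

The forward map numbers the non-leaf vertices of a forest on leaves 1..n
with n+1, n+2, ... by repeatedly picking, among unnumbered non-leaf vertices
all of whose children are numbered, the one with the numerically smallest
child; one root is left unnumbered.  Blocks of the resulting set partition
are the sibling sets (children of a common vertex); numbered roots and
isolated leaves contribute singleton blocks.

The inverse map rebuilds the forest from a set partition by repeatedly
attaching a new parent over the eligible non-trivial block (fully contained
in the labels laid down so far) that holds the smallest integer.

For a binary tree the partition is a perfect matching of [2n-2] and the
diagram lives in the Brauer set B_{n,n-2}; for a general tree it is a
no-singleton partition laid out on n top and l(pi)-1 bottom nodes; forests
add singleton blocks (one per numbered root / isolated leaf).
"""

from __future__ import annotations

from dataclasses import dataclass

from sympy.combinatorics import Permutation

from .diagram_core import PartitionDiagram, SetPartition, make_partition_diagram
from .errors import (
    MalformedPartitionError,
    NotAForestError,
    ValidationError,
)
from .trees_forests import Forest, PhyloTree, TreeNode

__all__ = [
    "DiagramClassification",
    "phylo_to_partition",
    "partition_to_forest",
    "dims_from_partition",
    "phylo_to_diagram",
    "diagram_to_phylo",
    "classify_diagram",
    "to_balanced",
    "from_balanced",
    "to_transpositions",
]


@dataclass(frozen=True)
class DiagramClassification:
    """Verdict on which phylogenetic object (if any) a diagram encodes.

    A no-singleton partition on an (n, m) frame is a tree iff
    m = l(pi) - 1; with s singleton blocks the object is a forest with
    tau = s + 1 components iff m = l(pi) - tau.  All blocks of size two on
    a valid tree frame means a binary tree.  The all-singleton (trivial)
    partition is the trivial forest, drawn with m = 0 and tau = n.
    """

    verdict: str  # binary_tree | tree | forest | invalid
    n: int
    m: int
    n_blocks: int
    n_nontrivial: int
    n_singletons: int
    tau: int | None

    @property
    def is_valid(self) -> bool:
        return self.verdict != "invalid"


# ---------------------------------------------------------------------------
# forest -> partition


def phylo_to_partition(forest: Forest) -> SetPartition:
    """Number non-leaf vertices and read off the sibling-set partition."""
    n = forest.n_leaves
    label_of: dict[int, int] = {}  # id(node) -> label
    internal: list[TreeNode] = []
    for tree in forest:
        for v in tree.root.walk():
            if v.is_leaf:
                label_of[id(v)] = v.label
            else:
                internal.append(v)

    # Assign n+1 .. n+M-1; the last eligible vertex (a root) stays unnumbered.
    next_label = n + 1
    unlabelled = [v for v in internal]
    for _ in range(max(len(internal) - 1, 0)):
        eligible = [
            v
            for v in unlabelled
            if all(id(c) in label_of for c in v.children)
        ]
        chosen = min(eligible, key=lambda v: min(label_of[id(c)] for c in v.children))
        label_of[id(chosen)] = next_label
        next_label += 1
        unlabelled.remove(chosen)

    blocks = [
        [label_of[id(c)] for c in v.children] for v in internal
    ]
    ground = n + max(len(internal) - 1, 0)
    covered = {x for b in blocks for x in b}
    blocks.extend([x] for x in range(1, ground + 1) if x not in covered)
    return SetPartition(ground, blocks)


# ---------------------------------------------------------------------------
# partition -> forest


def dims_from_partition(pi: SetPartition) -> tuple[int, int, int]:
    """Return (n leaves, m bottom nodes, tau components) for a partition.

    For a non-trivial partition: n = |pi| - l_{>=2}(pi) + 1,
    m = l_{>=2}(pi) - 1 and tau = (number of singletons) + 1.  The trivial
    partition of [t] encodes the trivial forest: n = t, m = 0, tau = t.
    """
    if pi.is_trivial:
        return pi.size, 0, pi.size
    n = pi.size - pi.n_nontrivial + 1
    m = pi.n_nontrivial - 1
    tau = len(pi.singletons) + 1
    return n, m, tau


def partition_to_forest(pi: SetPartition) -> Forest:
    """Rebuild the forest encoded by a set partition of {1..t}."""
    n, _, _ = dims_from_partition(pi)
    if pi.is_trivial:
        return Forest(PhyloTree(TreeNode(label=i)) for i in range(1, n + 1))

    nodes: dict[int, TreeNode] = {i: TreeNode(label=i) for i in range(1, n + 1)}
    has_parent: set[int] = set()
    remaining = [b for b in pi.blocks if len(b) >= 2]
    next_label = n + 1
    while remaining:
        eligible = [b for b in remaining if all(x in nodes for x in b)]
        if not eligible:
            raise MalformedPartitionError(
                f"no block of {remaining} lies within the assigned labels "
                f"1..{next_label - 1}; the input is not a partition of a "
                "contiguous ground set"
            )
        block = min(eligible, key=lambda b: b[0])
        remaining.remove(block)
        parent = TreeNode(children=[nodes[x] for x in block])
        has_parent.update(block)
        if remaining:
            nodes[next_label] = parent
            next_label += 1
        else:
            nodes[0] = parent  # the unnumbered root; key 0 is never a label

    roots = [node for lab, node in nodes.items() if lab not in has_parent]
    return Forest(PhyloTree(r) for r in roots)


# ---------------------------------------------------------------------------
# diagrams


def phylo_to_diagram(forest: Forest) -> PartitionDiagram:
    """Lay the forest's partition out on n top and |pi| - n bottom nodes."""
    pi = phylo_to_partition(forest)
    n = forest.n_leaves
    return PartitionDiagram(n, pi.size - n, pi)


def classify_diagram(alpha: PartitionDiagram) -> DiagramClassification:
    pi = alpha.partition
    n, m = alpha.n_top, alpha.m_bottom
    s = len(pi.singletons)
    if pi.is_trivial:
        verdict = "forest" if m == 0 else "invalid"
        tau = n if verdict == "forest" else None
        return DiagramClassification(verdict, n, m, pi.n_blocks, 0, s, tau)
    tau = s + 1
    if m != pi.n_blocks - tau:  # equivalently m != l_{>=2}(pi) - 1
        return DiagramClassification(
            "invalid", n, m, pi.n_blocks, pi.n_nontrivial, s, None
        )
    if s == 0:
        verdict = "binary_tree" if pi.is_matching else "tree"
        tau = 1
    else:
        verdict = "forest"
    return DiagramClassification(
        verdict, n, m, pi.n_blocks, pi.n_nontrivial, s, tau
    )


def diagram_to_phylo(alpha: PartitionDiagram) -> Forest:
    """Inverse of :func:`phylo_to_diagram`; raises if the diagram is invalid."""
    cls = classify_diagram(alpha)
    if not cls.is_valid:
        raise NotAForestError(
            f"diagram ({alpha.n_top},{alpha.m_bottom}) violates the forest "
            f"condition m = l(pi) - tau: l(pi)={cls.n_blocks}, "
            f"singletons={cls.n_singletons}, m={alpha.m_bottom}",
            diagram=alpha,
            classification=cls,
        )
    return partition_to_forest(alpha.partition)


# ---------------------------------------------------------------------------
# balanced / unbalanced Brauer presentations and transpositions


def to_balanced(alpha: PartitionDiagram) -> PartitionDiagram:
    """Reinterpret a B_{n,n-2} matching diagram as its balanced B_{n-1} twin.

    The underlying matching of [2n-2] is unchanged; only the frame moves,
    from n top / n-2 bottom to n-1 top / n-1 bottom (clockwise labelling in
    both cases).
    """
    if not alpha.is_brauer:
        raise ValidationError("to_balanced requires a Brauer (matching) diagram")
    if alpha.m_bottom != alpha.n_top - 2:
        raise ValidationError(
            f"expected an (n, n-2) diagram, got ({alpha.n_top},{alpha.m_bottom})"
        )
    half = alpha.n_top - 1
    return PartitionDiagram(half, half, alpha.partition)


def from_balanced(beta: PartitionDiagram) -> PartitionDiagram:
    """Inverse of :func:`to_balanced`."""
    if not beta.is_brauer:
        raise ValidationError("from_balanced requires a Brauer (matching) diagram")
    if beta.m_bottom != beta.n_top:
        raise ValidationError(
            f"expected a balanced diagram, got ({beta.n_top},{beta.m_bottom})"
        )
    n = beta.n_top + 1
    return PartitionDiagram(n, n - 2, beta.partition)


def to_transpositions(matching: SetPartition) -> Permutation:
    """The fixed-point-free involution of a perfect matching.

    Returns a sympy Permutation, which is 0-indexed: matching label i acts
    at index i - 1, so the block {i, j} becomes the cycle (i-1, j-1).
    """
    if not matching.is_matching:
        raise ValidationError("to_transpositions requires a perfect matching")
    cycles = [[i - 1, j - 1] for i, j in matching.blocks]
    return Permutation(cycles, size=matching.size)
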