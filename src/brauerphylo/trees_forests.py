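"""Rooted phylogenetic trees and forests with Newick I/O.

A rooted phylogenetic tree has leaves bijectively labelled by positive
integers and unlabelled non-leaf vertices, every one of which has out-degree
at least 2 (binary trees: exactly 2).  The single-vertex *trivial* tree — an
isolated labelled leaf that is also the root — is allowed as a forest
component.  A forest is a set of such trees whose leaf label sets partition
{1..n}.

Newick text is the external format: one semicolon-terminated statement per
component, parsed through dendropy.  Output is canonical — children are
ordered by their smallest descendant leaf label, components by their
smallest leaf — so serialization is byte-stable and ``parse_newick`` /
``write_newick`` are mutually inverse on canonical text.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

from .errors import ValidationError

__all__ = [
    "TreeNode",
    "PhyloTree",
    "Forest",
    "StructureStats",
    "parse_newick",
    "write_newick",
    "structure_stats",
]

logger = logging.getLogger(__name__)


@dataclass
class TreeNode:
    """A vertex: leaves carry an integer ``label``, internal vertices None."""

    label: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def min_leaf(self) -> int:
        if self.is_leaf:
            return self.label  # type: ignore[return-value]
        return min(c.min_leaf() for c in self.children)

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


class PhyloTree:
    """A rooted phylogenetic tree.  Canonicalized and validated on build."""

    __slots__ = ("root",)

    def __init__(self, root: TreeNode):
        _canonicalize(root)
        _validate_tree(root)
        object.__setattr__(self, "root", root)

    def __setattr__(self, name, value):
        raise AttributeError("PhyloTree is immutable")

    @property
    def is_trivial(self) -> bool:
        """A single labelled leaf that is also the root."""
        return self.root.is_leaf

    @property
    def leaf_labels(self) -> frozenset[int]:
        return frozenset(v.label for v in self.root.walk() if v.is_leaf)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_internal(self) -> int:
        """Number of non-leaf vertices, root included."""
        return sum(1 for v in self.root.walk() if not v.is_leaf)

    @property
    def is_binary(self) -> bool:
        return all(
            len(v.children) == 2 for v in self.root.walk() if not v.is_leaf
        )

    def min_leaf(self) -> int:
        return self.root.min_leaf()

    def newick(self) -> str:
        return _node_newick(self.root) + ";"

    def __eq__(self, other) -> bool:
        return isinstance(other, PhyloTree) and self.newick() == other.newick()

    def __hash__(self) -> int:
        return hash(self.newick())

    def __repr__(self) -> str:
        return f"PhyloTree({self.newick()!r})"


class Forest:
    """A set of rooted trees whose leaf label sets partition {1..n}."""

    __slots__ = ("trees",)

    def __init__(self, trees: Iterable[PhyloTree]):
        ordered = tuple(sorted(trees, key=lambda t: t.min_leaf()))
        if not ordered:
            raise ValidationError("a forest needs at least one component")
        labels: list[int] = []
        for t in ordered:
            labels.extend(t.leaf_labels)
        n = len(labels)
        if len(set(labels)) != n:
            raise ValidationError("duplicate leaf labels across forest components")
        if set(labels) != set(range(1, n + 1)):
            raise ValidationError(
                f"leaf labels must be exactly 1..{n}, got {sorted(set(labels))}"
            )
        object.__setattr__(self, "trees", ordered)

    def __setattr__(self, name, value):
        raise AttributeError("Forest is immutable")

    @property
    def n_leaves(self) -> int:
        return sum(t.n_leaves for t in self.trees)

    @property
    def n_components(self) -> int:
        """tau: number of component trees."""
        return len(self.trees)

    @property
    def is_trivial(self) -> bool:
        return all(t.is_trivial for t in self.trees)

    @property
    def is_single_tree(self) -> bool:
        return len(self.trees) == 1 and not self.trees[0].is_trivial

    def single_tree(self) -> PhyloTree:
        if len(self.trees) != 1:
            raise ValidationError(
                f"forest has {len(self.trees)} components, expected a single tree"
            )
        return self.trees[0]

    def newick(self) -> str:
        return "\n".join(t.newick() for t in self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)

    def __eq__(self, other) -> bool:
        return isinstance(other, Forest) and self.newick() == other.newick()

    def __hash__(self) -> int:
        return hash(self.newick())

    def __repr__(self) -> str:
        return f"Forest({self.newick()!r})"


@dataclass(frozen=True)
class StructureStats:
    """Cherry and shape summary of a tree.

    ``cherries`` holds, per non-leaf vertex with at least two leaf children,
    the frozenset of those leaf labels.  For a binary tree on n leaves the
    Brauer rank of its diagram is n - 2 * (number of cherries).
    """

    cherries: frozenset[frozenset[int]]
    n_leaves: int
    n_internal: int
    is_binary: bool

    @property
    def n_cherries(self) -> int:
        return len(self.cherries)

    @property
    def predicted_rank(self) -> int:
        return self.n_leaves - 2 * self.n_cherries


# ---------------------------------------------------------------------------
# internals


def _canonicalize(node: TreeNode) -> int:
    """Recursively order children by smallest descendant leaf; return min."""
    if node.is_leaf:
        if node.label is None:
            raise ValidationError("leaf without a label")
        return node.label
    keyed = sorted((_canonicalize(c), c) for c in node.children)
    node.children = [c for _, c in keyed]
    return keyed[0][0]


def _validate_tree(root: TreeNode) -> None:
    labels: set[int] = set()
    for v in root.walk():
        if v.is_leaf:
            if not isinstance(v.label, int) or v.label < 1:
                raise ValidationError(
                    f"leaf labels must be positive integers, got {v.label!r}"
                )
            if v.label in labels:
                raise ValidationError(f"duplicate leaf label {v.label}")
            labels.add(v.label)
        elif len(v.children) < 2:
            raise ValidationError(
                "internal vertex of out-degree 1 is not allowed in a "
                "phylogenetic tree"
            )


def _node_newick(node: TreeNode) -> str:
    if node.is_leaf:
        return str(node.label)
    return "(" + ",".join(_node_newick(c) for c in node.children) + ")"


def _convert_dendropy(dnode: "dendropy.Node") -> TreeNode:
    children = dnode.child_nodes()
    if not children:
        raw = dnode.taxon.label if dnode.taxon is not None else dnode.label
        try:
            label = int(raw)
        except (TypeError, ValueError):
            raise ValidationError(
                f"leaf label {raw!r} is not an integer"
            ) from None
        return TreeNode(label=label)
    return TreeNode(children=[_convert_dendropy(c) for c in children])


# ---------------------------------------------------------------------------
# public operations


def parse_newick(text: str) -> Forest:
    """Parse (multi-statement) Newick text into a validated Forest.

    Branch lengths and internal node labels are tolerated on input and
    dropped from the model (topologies only); a warning is logged if branch
    lengths are present.
    """
    try:
        tree_list = dendropy.TreeList.get(
            file=io.StringIO(text), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"malformed Newick: {exc}") from exc
    if not tree_list:
        raise ValidationError("no Newick statements found")
    if any(
        edge.length is not None
        for dtree in tree_list
        for edge in dtree.preorder_edge_iter()
    ):
        logger.warning("branch lengths present in Newick input; ignored")
    trees = [PhyloTree(_convert_dendropy(t.seed_node)) for t in tree_list]
    return Forest(trees)


def write_newick(forest: Forest) -> str:
    """Canonical Newick, one statement per component."""
    return forest.newick()


def structure_stats(tree: PhyloTree) -> StructureStats:
    cherries = set()
    for v in tree.root.walk():
        if not v.is_leaf:
            leaf_children = frozenset(c.label for c in v.children if c.is_leaf)
            if len(leaf_children) >= 2:
                cherries.add(leaf_children)
    return StructureStats(
        cherries=frozenset(cherries),
        n_leaves=tree.n_leaves,
        n_internal=tree.n_internal,
        is_binary=tree.is_binary,
    )
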