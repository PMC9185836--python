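"""Actions, Green's relations, sandwich products, regularity, idempotents.

The unbalanced diagrams B_{n,n-2} do not compose among themselves, but the
symmetric group S_n acts on their tops, S_{n-2} on their bottoms, and a
fixed tree diagram T turns the whole set into a *sandwich semigroup* with
product a *_T b = a . T-bar . b, where T-bar is T flipped about the
horizontal axis.

Restricted Green's relations under those group actions decompose tree space
into an eggbox: L-classes share a bottom half, R-classes a top half,
H-classes both, and D-classes (the L-or-R join) collect all diagrams of one
rank.  Regular elements of the sandwich semigroup (x with x a x = x for
some a) are detected either by rank preservation under T-bar . x . T-bar or
by the join/separation criterion on kernels and cokernels; the closed-form
count sums double-factorial terms over ranks j <= k of matching parity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Iterator

from .bijections import (
    classify_diagram,
    diagram_to_phylo,
    from_balanced,
    phylo_to_diagram,
    to_balanced,
    DiagramClassification,
)
from .diagram_core import (
    Equivalence,
    PartitionDiagram,
    SetPartition,
    analyze,
    compose,
    flip,
    join_equivalences,
    make_partition_diagram,
    separates,
)
from .errors import DimensionMismatchError, NotATreeError, ValidationError
from .trees_forests import Forest, PhyloTree

__all__ = [
    "GeneratorElement",
    "SandwichContext",
    "Eggbox",
    "act_top",
    "act_bottom",
    "green_class_key",
    "eggbox",
    "sandwich_product",
    "is_regular",
    "regular_count_formula",
    "regular_elements",
    "idempotents",
    "tree_product_balanced",
    "tree_involution",
    "double_factorial",
]

ENUMERATION_GUARD = 10  # (2n-3)!! growth; larger n needs force=True


def double_factorial(x: int) -> int:
    """x!! with the conventions (-1)!! = 0!! = 1."""
    if x < -1:
        raise ValidationError(f"double factorial undefined for {x}")
    result = 1
    while x > 1:
        result *= x
        x -= 2
    return result


@dataclass(frozen=True)
class GeneratorElement:
    """A generator of the balanced diagram monoid of a given ambient size.

    kind 's': the transposition diagram swapping strands i, i+1.
    kind 'e': the cup/cap (Temperley-Lieb) diagram at strands i, i+1.
    kind 'permutation': an arbitrary permutation diagram; ``perm`` maps top
    position -> bottom position (1-based dict).
    """

    kind: str
    index: int | None = None
    perm: tuple[int, ...] | None = None  # perm[i-1] = image of i
    size: int = 0

    def __post_init__(self):
        if self.kind in ("s", "e"):
            if self.index is None or not 1 <= self.index <= self.size - 1:
                raise ValidationError(
                    f"generator index must lie in 1..{self.size - 1}"
                )
        elif self.kind == "permutation":
            if self.perm is None or sorted(self.perm) != list(
                range(1, self.size + 1)
            ):
                raise ValidationError("perm must be a permutation of 1..size")
        else:
            raise ValidationError(f"unknown generator kind {self.kind!r}")

    def diagram(self) -> PartitionDiagram:
        """The balanced (size, size) diagram of this generator."""
        n = self.size
        total = 2 * n

        def bottom(pos: int) -> int:  # clockwise labelling
            return total + 1 - pos

        if self.kind == "permutation":
            blocks = [[i, bottom(self.perm[i - 1])] for i in range(1, n + 1)]
        else:
            i = self.index
            blocks = []
            for j in range(1, n + 1):
                if j in (i, i + 1):
                    continue
                blocks.append([j, bottom(j)])
            if self.kind == "s":
                blocks += [[i, bottom(i + 1)], [i + 1, bottom(i)]]
            else:
                blocks += [[i, i + 1], [bottom(i), bottom(i + 1)]]
        return make_partition_diagram(n, n, blocks)

    @classmethod
    def identity(cls, size: int) -> "GeneratorElement":
        return cls(kind="permutation", perm=tuple(range(1, size + 1)), size=size)


def act_top(g: GeneratorElement, alpha: PartitionDiagram) -> PartitionDiagram:
    """Left action: compose the generator's diagram on top of alpha.

    Loops created by the gluing are discarded (loop parameter 1).
    """
    if g.size != alpha.n_top:
        raise DimensionMismatchError(
            f"generator of size {g.size} cannot act on top of an "
            f"({alpha.n_top},{alpha.m_bottom}) diagram"
        )
    return compose(g.diagram(), alpha)[0]


def act_bottom(alpha: PartitionDiagram, g: GeneratorElement) -> PartitionDiagram:
    """Right action: compose the generator's diagram below alpha."""
    if g.size != alpha.m_bottom:
        raise DimensionMismatchError(
            f"generator of size {g.size} cannot act on bottom of an "
            f"({alpha.n_top},{alpha.m_bottom}) diagram"
        )
    return compose(alpha, g.diagram())[0]


# ---------------------------------------------------------------------------
# Green's relations


def _top_half(alpha: PartitionDiagram) -> frozenset[frozenset[int]]:
    """Blocks restricted to the top row (transversals become stubs)."""
    return frozenset(
        frozenset(x for x in b if alpha.is_top(x))
        for b in alpha.blocks
        if any(alpha.is_top(x) for x in b)
    )


def _bottom_half(alpha: PartitionDiagram) -> frozenset[frozenset[int]]:
    return frozenset(
        frozenset(x for x in b if not alpha.is_top(x))
        for b in alpha.blocks
        if any(not alpha.is_top(x) for x in b)
    )


def green_class_key(alpha: PartitionDiagram, relation: str):
    """Hashable key identifying alpha's class under L, R, H or D.

    Two diagrams are related iff their keys are equal: L-classes share the
    bottom half, R-classes the top half, H both, and D the rank.
    """
    if relation == "L":
        return _bottom_half(alpha)
    if relation == "R":
        return _top_half(alpha)
    if relation == "H":
        return (_top_half(alpha), _bottom_half(alpha))
    if relation == "D":
        return analyze(alpha).rank
    raise ValidationError(f"unknown Green relation {relation!r}")


@dataclass(frozen=True)
class Eggbox:
    """Census of one D-class (all binary-tree diagrams of a given rank)."""

    n: int
    rank: int
    n_rows: int  # L-classes
    n_cols: int  # R-classes
    h_size: int
    total: int

    @property
    def n_h_classes(self) -> int:
        return self.n_rows * self.n_cols


def eggbox(n: int, k: int) -> Eggbox:
    """Eggbox census of the rank-k D-class of B_{n,n-2}.

    Requires 0 <= k <= n-2 with k = n (mod 2); every H-class has size k!.
    """
    from .enumeration import all_brauer_diagrams

    if not (0 <= k <= n - 2) or (n - k) % 2 != 0:
        raise ValidationError(
            f"rank {k} incompatible with n={n}: need 0 <= k <= n-2, k = n mod 2"
        )
    rows: set = set()
    cols: set = set()
    h_census: dict = {}
    total = 0
    for alpha in all_brauer_diagrams(n):
        if analyze(alpha).rank != k:
            continue
        total += 1
        rows.add(green_class_key(alpha, "L"))
        cols.add(green_class_key(alpha, "R"))
        key = green_class_key(alpha, "H")
        h_census[key] = h_census.get(key, 0) + 1
    h_sizes = set(h_census.values())
    expected = math.factorial(k)
    if h_sizes and h_sizes != {expected}:
        raise AssertionError(
            f"H-class sizes {h_sizes} deviate from k! = {expected}"
        )
    return Eggbox(
        n=n, rank=k, n_rows=len(rows), n_cols=len(cols), h_size=expected, total=total
    )


# ---------------------------------------------------------------------------
# sandwich semigroup


class SandwichContext:
    """A fixed tree diagram T with its cached flip.

    The usual context is a binary tree in B_{n,n-2} (required by the
    regularity and idempotent machinery); non-binary tree diagrams are also
    accepted so that mixed sandwich products, which can leave tree space,
    can be formed.
    """

    __slots__ = ("tree_diagram", "flipped", "rank", "n")

    def __init__(self, tree_diagram: PartitionDiagram):
        cls = classify_diagram(tree_diagram)
        if cls.verdict not in ("binary_tree", "tree"):
            raise NotATreeError(
                "sandwich context requires a single-tree diagram",
                diagram=tree_diagram,
                classification=cls,
            )
        object.__setattr__(self, "tree_diagram", tree_diagram)
        object.__setattr__(self, "flipped", flip(tree_diagram))
        object.__setattr__(self, "rank", analyze(tree_diagram).rank)
        object.__setattr__(self, "n", tree_diagram.n_top)

    def __setattr__(self, name, value):
        raise AttributeError("SandwichContext is immutable")

    @classmethod
    def from_tree(cls, tree: PhyloTree) -> "SandwichContext":
        return cls(phylo_to_diagram(Forest([tree])))

    @classmethod
    def from_matching(cls, n: int, blocks: Iterable[Iterable[int]]) -> "SandwichContext":
        return cls(make_partition_diagram(n, n - 2, blocks))


def sandwich_product(
    a: PartitionDiagram, b: PartitionDiagram, ctx: SandwichContext
) -> tuple[PartitionDiagram, DiagramClassification]:
    """a *_T b = a . T-bar . b, with the classification of the result.

    The product of two valid tree/forest diagrams can leave tree space (or
    even forest space), so the classification travels with the diagram.
    """
    left, _ = compose(a, ctx.flipped)
    result, _ = compose(left, b)
    return result, classify_diagram(result)


def _positional_bottom(alpha: PartitionDiagram, labels: Iterable[int]) -> list[int]:
    return [alpha.bottom_position(x) for x in labels]


def is_regular(
    alpha: PartitionDiagram, ctx: SandwichContext, method: str = "rank"
) -> bool:
    """Is alpha a regular element of the sandwich semigroup at ctx?

    method='rank': alpha is regular iff T-bar . alpha . T-bar has the same
    rank as alpha.

    method='separation': alpha is regular iff coker(alpha) v ker(T-bar)
    separates codom(alpha) and ker(alpha) v coker(T-bar) separates
    dom(alpha).  Cross-diagram relations are compared positionally: bottom
    labels are mapped to left-to-right positions 1..n-2, top labels are
    already positional.
    """
    if not ctx.tree_diagram.is_brauer or ctx.tree_diagram.m_bottom != ctx.n - 2:
        raise ValidationError(
            "regularity theory requires a binary-tree context in B_{n,n-2}"
        )
    if alpha.n_top != ctx.n or alpha.m_bottom != ctx.n - 2:
        raise DimensionMismatchError(
            f"diagram ({alpha.n_top},{alpha.m_bottom}) incompatible with "
            f"sandwich context on n={ctx.n}"
        )
    if method == "rank":
        inner, _ = compose(ctx.flipped, alpha)
        outer, _ = compose(inner, ctx.flipped)
        return analyze(outer).rank == analyze(alpha).rank
    if method == "separation":
        n = ctx.n
        a_stats = analyze(alpha)
        t_stats = analyze(ctx.flipped)
        bottom_ground = range(1, n - 1)
        top_ground = range(1, n + 1)
        # condition 1: coker(alpha) v ker(T-bar) separates codom(alpha)
        coker_a = Equivalence(
            bottom_ground,
            [_positional_bottom(alpha, c) for c in a_stats.coker_classes()],
        )
        ker_tbar = Equivalence(bottom_ground, t_stats.ker_classes())
        cond1 = separates(
            join_equivalences(coker_a, ker_tbar),
            _positional_bottom(alpha, a_stats.codom),
        )
        # condition 2: ker(alpha) v coker(T-bar) separates dom(alpha)
        ker_a = Equivalence(top_ground, a_stats.ker_classes())
        coker_tbar = Equivalence(
            top_ground,
            [_positional_bottom(ctx.flipped, c) for c in t_stats.coker_classes()],
        )
        cond2 = separates(join_equivalences(ker_a, coker_tbar), a_stats.dom)
        return cond1 and cond2
    raise ValidationError(f"unknown regularity method {method!r}")


def regular_count_formula(n: int, k: int) -> int:
    """Closed-form size of the regular subsemigroup for a rank-k context.

    Sums, over ranks j <= k of the same parity as k,

        C(k,j)^2 ((k-j-1)!!)^2 (n+j-1)!! (n+j-3)!! j! / ((k+j-1)!!)^2.
    """
    if not (0 <= k <= n - 2) or (n - k) % 2 != 0:
        raise ValidationError(
            f"rank {k} incompatible with n={n}: need 0 <= k <= n-2, k = n mod 2"
        )
    total = Fraction(0)
    for j in range(k % 2, k + 1, 2):
        term = Fraction(
            math.comb(k, j) ** 2
            * double_factorial(k - j - 1) ** 2
            * double_factorial(n + j - 1)
            * double_factorial(n + j - 3)
            * math.factorial(j),
            double_factorial(k + j - 1) ** 2,
        )
        total += term
    assert total.denominator == 1
    return int(total)


def _guard(n: int, force: bool) -> None:
    if n > ENUMERATION_GUARD and not force:
        raise ValidationError(
            f"exhaustive enumeration over (2n-3)!! diagrams refused for "
            f"n={n} > {ENUMERATION_GUARD}; pass force=True to override"
        )


def regular_elements(
    ctx: SandwichContext, method: str = "rank", force: bool = False
) -> Iterator[PartitionDiagram]:
    """All regular elements of the sandwich semigroup at ctx."""
    from .enumeration import all_brauer_diagrams

    _guard(ctx.n, force)
    for alpha in all_brauer_diagrams(ctx.n):
        if is_regular(alpha, ctx, method):
            yield alpha


def idempotents(ctx: SandwichContext, force: bool = False) -> Iterator[PartitionDiagram]:
    """All x in B_{n,n-2} with x *_T x = x."""
    from .enumeration import all_brauer_diagrams

    _guard(ctx.n, force)
    for alpha in all_brauer_diagrams(ctx.n):
        if sandwich_product(alpha, alpha, ctx)[0] == alpha:
            yield alpha


# ---------------------------------------------------------------------------
# induced products on trees


def tree_product_balanced(t1: PhyloTree, t2: PhyloTree) -> PhyloTree:
    """Product of two binary trees through their balanced Brauer diagrams.

    Both trees map to B_{n-1}; their composition (loops dropped) is again a
    perfect matching of [2n-2] and therefore again a tree.
    """
    if t1.n_leaves != t2.n_leaves:
        raise DimensionMismatchError(
            f"trees on {t1.n_leaves} and {t2.n_leaves} leaves cannot be multiplied"
        )
    for t in (t1, t2):
        if not t.is_binary:
            raise NotATreeError("balanced tree product requires binary trees")
    d1 = to_balanced(phylo_to_diagram(Forest([t1])))
    d2 = to_balanced(phylo_to_diagram(Forest([t2])))
    product, _ = compose(d1, d2)
    unbalanced = from_balanced(product)
    cls = classify_diagram(unbalanced)
    if cls.verdict != "binary_tree":  # defensive; cannot occur for matchings
        raise NotATreeError(
            "product diagram is not a binary-tree diagram",
            diagram=unbalanced,
            classification=cls,
        )
    return diagram_to_phylo(unbalanced).single_tree()


def tree_involution(t: PhyloTree) -> PhyloTree:
    """The *-involution: flip the balanced diagram and pull back to a tree."""
    if not t.is_binary:
        raise NotATreeError("the *-involution is defined for binary trees")
    balanced = to_balanced(phylo_to_diagram(Forest([t])))
    flipped = flip(balanced)
    return diagram_to_phylo(from_balanced(flipped)).single_tree()
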