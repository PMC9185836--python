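# Methods

## Objects and conventions

A rooted phylogenetic tree has integer-labelled leaves, unlabelled non-leaf
vertices of out-degree ≥ 2 (binary: exactly 2), and a root that is not
counted as an internal vertex.  The single-vertex tree (an isolated
labelled leaf) is allowed as a forest component; a forest's leaf label sets
partition {1..n}.

A partition diagram lays a set partition of {1..n+m} out on two rows.  The
layout convention matters and is fixed throughout: top nodes are labelled
1..n left-to-right, bottom nodes n+1..n+m **right-to-left**, continuing the
numbering clockwise around the frame.  This is the only layout under which
(a) the worked six-leaf example produces dom = {1,5}, codom = {7,10} on its
(6,4) frame, and (b) the same matching, reframed on 5+5 nodes, is literally
symmetric under reflection — which is what makes that tree a fixed point of
the ∗-involution.  Under this convention the horizontal reflection of an
(n, m) diagram is simply the label map x ↦ n+m+1−x on an (m, n) frame,
which is how `flip` is implemented.

Composition glues the upper diagram's bottom row to the lower diagram's top
row **by left-to-right position**, not by label (the bottom row of the
upper diagram reads n+m, n+m−1, … left-to-right, and is treated as
positions 1′, 2′, …).  Blocks are merged by union–find over the glued
nodes; components that end up entirely in the middle row are deleted and
counted.  The loop parameter is fixed at 1, so loops carry no weight, but
`compose` returns their count so that a general-loop-parameter extension
would need no interface change.  All cross-diagram comparisons of bottom
rows (Green's keys, the separation criterion) are likewise normalized to
positional indices.

Diagram equality is by canonical block set (blocks sorted ascending,
ordered by minimum element); that canonical order is also the text
serialization `n=6;m=4;blocks=1,10|2,3|4,6|5,7|8,9` and its JSON twin.

## The bijections

**Forest → partition.**  Non-leaf vertices are numbered n+1, n+2, … by
repeatedly choosing, among unnumbered vertices whose children are all
numbered, the one whose smallest child label is least; exactly one root is
left unnumbered.  Blocks are the sibling sets; numbered roots and isolated
leaves become singleton blocks.  Children sets are disjoint, so the
minimum-child rule has no ties and the procedure is fully deterministic.

**Partition → forest.**  Given a partition π of {1..t} with at least one
non-trivial block, the leaf count is n = |π| − ℓ≥2(π) + 1 where ℓ≥2 counts
blocks of size ≥ 2.  Starting from n labelled leaves, repeatedly take the
non-trivial block that (i) lies entirely inside the labels placed so far
and (ii) contains the smallest integer among such blocks, attach a new
parent over it, and give the parent the next label — except for the last
parent, which remains the unnumbered root.  A disjointness count shows an
eligible block always exists, so the construction never gets stuck on a
genuine partition; the corresponding error path is defensive.  Singletons
≤ n are isolated-leaf components; singletons > n are numbered roots.

**Frames.**  The partition of a forest on n leaves is drawn with n top and
|π| − n bottom nodes.  A diagram is a tree iff it has no singleton blocks
and m = ℓ(π) − 1; a forest with τ components iff it has τ − 1 singletons
and m = ℓ(π) − τ; a binary tree iff additionally every block is a pair.
The same partition can therefore be a tree on one frame and invalid on
another.

**Trivial-partition convention.**  The leaf-count formula
n = |π| − ℓ≥2(π) + 1 gives |π| + 1 for the all-singleton partition, yet the
trivial forest on n leaves maps forward to the trivial partition of [n].
We resolve the edge case in favour of the forward map: the trivial
partition of [t] encodes the trivial forest on t leaves, with m = 0 and
τ = t.  This keeps partition → forest → partition the identity on *every*
set partition (property-tested), at the cost of the displayed formula
having this one special case.

**Balanced twin.**  A binary tree's matching of [2n−2] can be framed either
as an unbalanced (n, n−2) diagram (leaves on top — the biologically
readable form) or as a balanced (n−1, n−1) diagram, where composition is a
total operation.  `to_balanced`/`from_balanced` move between frames without
touching the matching.  Because every balanced Brauer diagram on [2n−2]
*is* a perfect matching, the induced product of binary trees
T·T′ = δ⁻¹(δ(T)δ(T′)) is always defined and closed; the not-a-tree error
path of `tree_product_balanced` can only fire on malformed input.

## Green's relations and the sandwich semigroup

The restricted Green's relations act by S_n on tops and S_{n−2} on
bottoms.  Since the full symmetric group connects all same-rank
arrangements of one row, the classes are computable without orbit
enumeration: the L-key is the bottom half (coker blocks plus codom
positions), the R-key the top half, the H-key both, the D-key the rank.
Unit tests verify the keys against explicit breadth-first orbits under the
adjacent-transposition generators for n = 4, 5.  The D-relation is
implemented as the join of L and R (same-rank classes).  The literal
set-union reading of the D-class definition would not be an equivalence
relation; the join matches the stated interpretation of D-classes as "all
trees with the same number of cherries" and is what the census uses.

The sandwich product relative to a fixed tree T is a ∗_T b = a · T̄ · b.
Context objects accept any single-tree diagram (not only binary ones):
products with non-binary factors are exactly how stranded nodes and
count-condition violations arise, and the tests exhibit concrete products
whose results are a two-component forest and an invalid diagram
respectively.  The regularity machinery (rank-preservation test,
join/separation test, closed-form count) is restricted to binary-tree
contexts in B_{n,n−2}, which is the setting it is stated for.

The closed-form regular count for a rank-k context,

    Σ_{0≤j≤k, j≡k (2)} C(k,j)² ((k−j−1)!!)² (n+j−1)!! (n+j−3)!! j! / ((k+j−1)!!)²,

uses the convention (−1)!! = 1 (needed at j = k) and is evaluated in exact
rational arithmetic with an integrality assertion.  It is cross-checked
against brute force over all 945 six-leaf diagrams for context ranks 0, 2
and 4, and the two regularity tests are verified to agree exhaustively in
the same setting.

## Enumeration and random generation

Set partitions are enumerated by assigning the smallest unplaced element to
each existing block or a new one — canonical, duplicate-free, deterministic
order.  Counts of partitions with restricted block sizes use the recursion
f(t) = Σ_s C(t−1, s−1) f(t−s) over allowed sizes s (conditioning on the
block of the smallest element), the partial-Bell evaluation.  Partitions of
[t] into exactly ℓ blocks of size ≥ 2 are counted by the 2-associated
Stirling recursion b(t, ℓ) = ℓ·b(t−1, ℓ) + (t−1)·b(t−2, ℓ−1).

Binary trees are sampled uniformly by drawing a uniform perfect matching of
[2n−2] (pair the smallest unmatched element with a uniform partner); the
matching↔tree bijection makes the draw exactly uniform over the (2n−3)!!
labelled topologies with no rejection.  General trees are sampled uniformly
over all rooted phylogenetic trees on n leaves by first choosing the number
of internal vertices ℓ with probability ∝ b(n+ℓ−1, ℓ) and then sampling a
no-singleton partition with the same recursion run backwards.  Both
samplers take a seed or a `random.Random` and are reproducible.

Exhaustive operations refuse n > 10 without `force=True`, since the spaces
grow as (2n−3)!! and Bell numbers.

## Problem sizes and what the tests show

All quantitative claims are desk-scale integer combinatorics, reproduced
exactly: the 945 = 45 + 540 + 360 six-leaf rank census, the 6 × 45 × 2
rank-2 eggbox with 270 H-classes, the 765 = 45 + 504 + 216 regular census
(with 36 + 144 non-regulars split by domain size) of the rank-4 caterpillar
context, the 45 idempotents of rank-0 contexts, and the restricted
partition sequences 1, 1, 4, 11, 41, 162 and 1, 1, 3, 10, 25, 105, 385.
Exhaustive bijection round trips cover all binary and non-binary trees up
to six leaves and all forests up to five; algebra laws (associativity with
additive loop counts, the flip anti-homomorphism, rank monotonicity, the
loop-parameter-1 generator relations) are checked on seeded random diagrams
and all ambient sizes up to 6.  Uniformity of the binary sampler is tested
by a χ² goodness-of-fit over all 945 six-leaf topologies at 10⁶ draws
(α = 0.01) — a calibration check, not a proof, complementing the bijection
argument above.

The exhaustive checks stop at six leaves (n = 6 is where the worked
numbers live, and (2n−3)!! growth makes it the natural exhaustive
horizon); properties expected to hold at every n are additionally sampled
at random sizes up to 12.

## Known limitations

- Diagrams are treated as a monoid basis at loop parameter 1; no linear
  combinations, no general loop parameter (loop counts are exposed for a
  future extension).
- The D-class structure for non-binary trees and forests is richer than
  rank alone; `eggbox` covers the binary case only.
- Planarity restrictions, tree-metric constructions, and mid-identities
  are out of scope.
- Newick branch lengths and internal labels are parsed but discarded; the
  objects here are topologies.
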