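# brauerphylo

Algebraic machinery for rooted phylogenetic trees and forests built on
their correspondence with Brauer and partition diagrams.

A rooted binary phylogenetic tree on leaves 1..n determines a perfect
matching of {1..2n−2}: number the internal vertices n+1, n+2, … by always
picking the vertex whose children are all numbered and whose smallest child
label is least, then pair siblings.  Drawn with the n leaves on the top row
and the n−2 internal labels on the bottom row (numbered clockwise), the
matching becomes an unbalanced Brauer diagram in B_{n,n−2}.  Non-binary
trees generalize to set partitions with all blocks of size ≥ 2, and forests
to arbitrary set partitions (numbered roots and isolated leaves appear as
singleton blocks) — so the set of all forests is in bijection with the set
of all set partitions of finite sets.

The diagram picture equips tree space with algebra:

- **Diagram composition** with loop removal (loop parameter fixed at 1),
  the flip involution `α ↦ α*`, and the transversal analytics dom(α),
  codom(α), ker(α), coker(α), rank(α) = |dom(α)|.
- **Restricted Green's relations**: S_n acts on diagram tops, S_{n−2} on
  bottoms; L-classes share a bottom half, R-classes a top half, H-classes
  both (size k! at rank k), and D-classes collect all trees with the same
  number of cherries.  `eggbox(n, k)` computes the census.
- **The sandwich semigroup**: fixing a tree T with flipped diagram T̄, the
  product T₁ ∗_T T₂ := T₁ · T̄ · T₂ makes B_{n,n−2} a semigroup.  The
  regular elements (x with x·a·x = x for some a) are detected either by
  rank preservation under T̄·x·T̄ or by the join/separation criterion on
  kernels and cokernels, and counted in closed form by

      |Reg| = Σ_{0≤j≤k, j≡k (2)} C(k,j)² ((k−j−1)!!)² (n+j−1)!! (n+j−3)!! j! / ((k+j−1)!!)²

  for a context of rank k.  Idempotents (x ∗_T x = x) are enumerated by
  brute force.
- **Enumeration and sampling**: all binary trees via matchings, all trees
  and forests via restricted set partitions, partial-Bell counting of
  block-size-restricted partitions, and uniform random tree generators.

## Worked example

```python
>>> import brauerphylo as bp
>>> forest = bp.parse_newick("(1,((4,6),(5,(2,3))));")
>>> bp.phylo_to_partition(forest)
SetPartition(10, 1,10|2,3|4,6|5,7|8,9)
>>> stats = bp.analyze(bp.phylo_to_diagram(forest))
>>> sorted(stats.dom), sorted(stats.codom), stats.rank
([1, 5], [7, 10], 2)
```

The six-leaf tree maps to the matching {1,10}, {2,3}, {4,6}, {5,7}, {8,9}:
the cherries {2,3} and {4,6} pair up first, and the two transversals
(rank 2) start at leaves 1 and 5.  Rank 2 means 6 − 2·2 cherries.  This
particular tree equals its own ∗-involution because its balanced diagram is
symmetric under the flip.

From the shell:

```console
$ brauerphylo count --n 6 --by rank
{"0": 45, "2": 540, "4": 360}
$ brauerphylo green --n 6 --rank 2
{"n": 6, "rank": 2, "n_rows": 6, "n_cols": 45, "h_size": 2, "total": 540}
$ brauerphylo regular --ctx "(1,(2,(((3,4),6),5)));" --count
765
```

The 945 six-leaf binary trees split by rank into 45 + 540 + 360; the rank-2
D-class is a 6 × 45 eggbox of 270 two-element H-classes; and relative to
the rank-4 caterpillar context, 765 of the 945 trees are regular (the
formula and the brute-force census agree).

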