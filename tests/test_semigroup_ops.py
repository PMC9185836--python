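"""Group actions, Green's classes, sandwich products, regularity, idempotents."""

import math
import random
from collections import Counter

import pytest

from brauerphylo import (
    GeneratorElement,
    SandwichContext,
    SetPartition,
    ValidationError,
    act_bottom,
    act_top,
    all_brauer_diagrams,
    analyze,
    classify_diagram,
    compose,
    double_factorial,
    eggbox,
    flip,
    green_class_key,
    idempotents,
    is_regular,
    make_partition_diagram,
    parse_newick,
    partition_to_forest,
    phylo_to_diagram,
    regular_count_formula,
    regular_elements,
    sandwich_product,
    tree_involution,
    tree_product_balanced,
)

from conftest import (
    CATERPILLAR_MATCHING,
    SIX_LEAF_NEWICK,
    random_matching_diagram,
)


def s_gen(i, n):
    return GeneratorElement(kind="s", index=i, size=n)


def e_gen(i, n):
    return GeneratorElement(kind="e", index=i, size=n)


class TestActions:
    def test_transposition_on_its_own_cup_is_identity(self, six_leaf_diagram):
        # {2,3} is a top block, so s_2 fixes the diagram
        assert act_top(s_gen(2, 6), six_leaf_diagram) == six_leaf_diagram

    def test_identity_actions(self, six_leaf_diagram):
        assert act_top(GeneratorElement.identity(6), six_leaf_diagram) == six_leaf_diagram
        assert act_bottom(six_leaf_diagram, GeneratorElement.identity(4)) == six_leaf_diagram

    def test_bottom_transposition_on_positional_pair(self):
        # bottom positions 1,2 carry labels 10,9; the block {9,10} is the
        # positional pair {1,2}, so s_1 below fixes the diagram
        d = make_partition_diagram(6, 4, [[1, 7], [2, 8], [3, 4], [5, 6], [9, 10]])
        assert act_bottom(d, s_gen(1, 4)) == d

    def test_cup_action_can_leave_tree_space(self):
        # e_1 applied over a top block {1,2,6} strands the bottom node
        d = make_partition_diagram(5, 1, [[1, 2, 6], [3, 4, 5]])
        result = act_top(e_gen(1, 5), d)
        assert (6,) in result.blocks
        assert classify_diagram(result).verdict == "forest"

    def test_top_and_bottom_actions_commute(self):
        rng = random.Random(50100)
        for _ in range(200):
            n = rng.randint(3, 7)
            alpha = random_matching_diagram(rng, n, n - 2)
            g_top = s_gen(rng.randint(1, n - 1), n)
            g_bot = (
                s_gen(rng.randint(1, n - 3), n - 2)
                if n >= 4
                else GeneratorElement.identity(n - 2)
            )
            assert act_bottom(act_top(g_top, alpha), g_bot) == act_top(
                g_top, act_bottom(alpha, g_bot)
            )


class TestGreenRelations:
    def _orbit(self, start, generators, action):
        frontier = [start]
        seen = {start}
        while frontier:
            nxt = []
            for d in frontier:
                for g in generators:
                    image = action(g, d)
                    if image not in seen:
                        seen.add(image)
                        nxt.append(image)
            frontier = nxt
        return seen

    @pytest.mark.parametrize("n", [4, 5])
    def test_keys_match_orbits(self, n):
        """L/R-classes computed by key equal orbits under the group actions."""
        diagrams = list(all_brauer_diagrams(n))
        top_gens = [s_gen(i, n) for i in range(1, n)]
        bot_gens = [s_gen(i, n - 2) for i in range(1, n - 2)]
        rng = random.Random(50101 + n)
        for start in rng.sample(diagrams, 5):
            l_orbit = self._orbit(start, top_gens, act_top)
            l_class = {
                d
                for d in diagrams
                if green_class_key(d, "L") == green_class_key(start, "L")
            }
            assert l_orbit == l_class
            if bot_gens:
                r_orbit = self._orbit(
                    start, bot_gens, lambda g, d: act_bottom(d, g)
                )
                r_class = {
                    d
                    for d in diagrams
                    if green_class_key(d, "R") == green_class_key(start, "R")
                }
                assert r_orbit == r_class

    def test_h_class_members_share_both_halves(self, six_leaf_diagram):
        relabelled = act_top(s_gen(2, 6), six_leaf_diagram)
        for rel in "LRHD":
            assert green_class_key(relabelled, rel) == green_class_key(
                six_leaf_diagram, rel
            )

    @pytest.mark.parametrize(
        "k, rows, cols, h, total",
        [(0, 3, 15, 1, 45), (2, 6, 45, 2, 540), (4, 1, 15, 24, 360)],
    )
    def test_six_leaf_eggboxes(self, k, rows, cols, h, total):
        box = eggbox(6, k)
        assert (box.n_rows, box.n_cols, box.h_size, box.total) == (
            rows,
            cols,
            h,
            total,
        )
        assert box.total == box.n_rows * box.n_cols * box.h_size

    def test_d_classes_partition_tree_space(self):
        census = Counter(analyze(d).rank for d in all_brauer_diagrams(6))
        assert census == {0: 45, 2: 540, 4: 360}
        assert sum(census.values()) == 945

    def test_parity_violation_rejected(self):
        with pytest.raises(ValidationError):
            eggbox(6, 1)
        with pytest.raises(ValidationError):
            eggbox(6, 6)


class TestSandwichProduct:
    def test_rank_bounded_by_all_three_factors(self, caterpillar_ctx):
        rng = random.Random(50102)
        for _ in range(200):
            a = random_matching_diagram(rng, 6, 4)
            b = random_matching_diagram(rng, 6, 4)
            result, _ = sandwich_product(a, b, caterpillar_ctx)
            assert analyze(result).rank <= min(
                analyze(a).rank, caterpillar_ctx.rank, analyze(b).rank
            )

    def test_tree_sandwich_squared_over_itself(self, six_leaf_diagram):
        ctx = SandwichContext(six_leaf_diagram)
        result, cls = sandwich_product(six_leaf_diagram, six_leaf_diagram, ctx)
        assert result == six_leaf_diagram
        assert cls.verdict == "binary_tree"

    def test_nonbinary_factor_can_strand_a_node(self, six_leaf_diagram):
        """A sandwich with a non-binary factor can produce a forest."""
        ctx = SandwichContext(six_leaf_diagram)
        a = make_partition_diagram(
            7, 4, [[1, 2], [3, 4], [5, 6], [7, 8], [9, 10, 11]]
        )
        assert classify_diagram(a).verdict == "tree"
        result, cls = sandwich_product(a, six_leaf_diagram, ctx)
        assert (11,) in result.blocks  # the stranded bottom node
        assert cls.verdict == "forest" and cls.tau == 2

    def test_two_nonbinary_factors_can_leave_forest_space(self, six_leaf_diagram):
        """The count condition m = l(pi) - tau can fail outright."""
        ctx = SandwichContext(six_leaf_diagram)
        a = make_partition_diagram(
            7, 4, [[1, 2, 3], [4, 5], [6, 7], [8, 9], [10, 11]]
        )
        b = make_partition_diagram(6, 2, [[1, 2, 3, 4], [5, 6], [7, 8]])
        assert classify_diagram(a).verdict == "tree"
        assert classify_diagram(b).verdict == "tree"
        result, cls = sandwich_product(a, b, ctx)
        assert cls.verdict == "invalid"
        # no singletons, so tau would be 1, yet m != l(pi) - 1
        assert cls.n_singletons == 0
        assert result.m_bottom != cls.n_blocks - 1


class TestRegularity:
    def test_worked_regular_census(self, caterpillar_ctx):
        regs = list(regular_elements(caterpillar_ctx))
        assert len(regs) == 765
        assert Counter(analyze(a).rank for a in regs) == {0: 45, 2: 504, 4: 216}
        nonreg = [
            a
            for a in all_brauer_diagrams(6)
            if not is_regular(a, caterpillar_ctx)
        ]
        assert Counter(len(analyze(a).dom) for a in nonreg) == {2: 36, 4: 144}

    def test_nonregularity_criterion_is_cherry_in_domain(self, caterpillar_ctx):
        # for this caterpillar context, alpha is non-regular iff {3,4} is
        # contained in dom(alpha)
        for alpha in all_brauer_diagrams(6):
            expected = not {3, 4} <= analyze(alpha).dom
            assert is_regular(alpha, caterpillar_ctx) is expected

    def test_context_tree_is_self_regular(self, caterpillar_ctx, six_leaf_diagram):
        assert is_regular(caterpillar_ctx.tree_diagram, caterpillar_ctx)
        ctx2 = SandwichContext(six_leaf_diagram)
        assert is_regular(six_leaf_diagram, ctx2)

    def test_all_rank0_diagrams_regular_for_caterpillar(self, caterpillar_ctx):
        rank0 = [d for d in all_brauer_diagrams(6) if analyze(d).rank == 0]
        assert len(rank0) == 45
        assert all(is_regular(d, caterpillar_ctx) for d in rank0)

    @pytest.mark.parametrize("ctx_rank", [0, 2, 4])
    def test_two_regularity_tests_agree_exhaustively(self, ctx_rank):
        ctx = next(
            SandwichContext(d)
            for d in all_brauer_diagrams(6)
            if analyze(d).rank == ctx_rank
        )
        for alpha in all_brauer_diagrams(6):
            assert is_regular(alpha, ctx, "rank") == is_regular(
                alpha, ctx, "separation"
            )

    @pytest.mark.parametrize("ctx_rank", [0, 2, 4])
    def test_formula_matches_brute_force(self, ctx_rank):
        ctx = next(
            SandwichContext(d)
            for d in all_brauer_diagrams(6)
            if analyze(d).rank == ctx_rank
        )
        brute = sum(1 for _ in regular_elements(ctx))
        assert regular_count_formula(6, ctx_rank) == brute

    def test_formula_summands_for_rank4(self):
        # the three parity-matched summands j=0,2,4 at n=6, k=4
        def term(j, n=6, k=4):
            return (
                math.comb(k, j) ** 2
                * double_factorial(k - j - 1) ** 2
                * double_factorial(n + j - 1)
                * double_factorial(n + j - 3)
                * math.factorial(j)
                // double_factorial(k + j - 1) ** 2
            )

        assert [term(j) for j in (0, 2, 4)] == [45, 504, 216]
        assert regular_count_formula(6, 4) == 765


class TestIdempotents:
    def test_rank0_context_has_45_idempotents(self, rank0_ctx):
        idems = list(idempotents(rank0_ctx))
        assert len(idems) == 45
        for x in idems:
            assert sandwich_product(x, x, rank0_ctx)[0] == x

    def test_idempotent_count_is_rank_invariant(self, rank0_ctx):
        other = SandwichContext.from_matching(
            6, [[1, 6], [2, 3], [4, 5], [7, 10], [8, 9]]
        )
        assert other.rank == 0
        assert sum(1 for _ in idempotents(other)) == sum(
            1 for _ in idempotents(rank0_ctx)
        )

    def test_idempotents_are_regular(self, caterpillar_ctx):
        regs = set(regular_elements(caterpillar_ctx))
        assert set(idempotents(caterpillar_ctx)) <= regs


class TestTreeProducts:
    def test_involution_fixes_symmetric_tree(self):
        tree = parse_newick(SIX_LEAF_NEWICK).single_tree()
        assert tree_involution(tree) == tree

    def test_involution_is_an_involution(self):
        from brauerphylo import random_phylo

        rng = random.Random(50103)
        for _ in range(200):
            tree = random_phylo(rng.randint(2, 9), rng, "binary").single_tree()
            assert tree_involution(tree_involution(tree)) == tree

    def test_product_is_associative(self):
        from brauerphylo import random_phylo

        rng = random.Random(50104)
        for _ in range(100):
            n = rng.randint(3, 7)
            t1, t2, t3 = (
                random_phylo(n, rng, "binary").single_tree() for _ in range(3)
            )
            left = tree_product_balanced(tree_product_balanced(t1, t2), t3)
            right = tree_product_balanced(t1, tree_product_balanced(t2, t3))
            assert left == right

    def test_product_of_caterpillar_context_tree(self, caterpillar_ctx):
        tree = partition_to_forest(
            SetPartition(10, CATERPILLAR_MATCHING)
        ).single_tree()
        product = tree_product_balanced(tree, tree)
        assert product.n_leaves == 6
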