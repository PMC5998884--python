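"""UME solvers: gnaw, exact class enumeration, bounds, heuristic, oracle."""
import pytest

import ume

from conftest import make_rng, random_instance_unrooted


class TestNaive:
    def test_example_scores_four(self, species, example_unrooted):
        res = ume.naive_ume([example_unrooted], species)
        assert res.score == 4

    def test_every_plateau_rooting_of_example_costs_four(self, species,
                                                         example_unrooted):
        U = example_unrooted
        info = ume.plateau(U, species)
        for e in info.edges:
            assert ume.rme_score([U.root_at(e)], species).score == 4

    def test_duplication_free_rooting_scores_zero(self):
        S = ume.parse_newick("((a,b),c);", "species")
        U = ume.parse_newick("(a,b,c);", "unrooted")
        assert ume.naive_ume([U], S).score == 0

    def test_limit_enforced(self, species, example_unrooted):
        with pytest.raises(ume.BudgetExceededError):
            ume.naive_ume([example_unrooted] * 10, species, limit=100)


class TestGnaw:
    def test_example_largest_class(self, species, example_unrooted):
        U = example_unrooted
        cs = ume.equiv_classes(U, species)
        big = max(cs.classes, key=len)
        dec = ume.decompose_class(U, species, big, cs.plateau)
        score, per_edge, best = ume.gnaw(
            dec.reduced, list(dec.image_edges.values()), dec.delta, species)
        assert score == 4
        assert set(per_edge.values()) == {4}  # attained on every class edge

    def test_gnaw_equals_min_over_class_rootings(self):
        """gnaw on the reduced tree equals the minimum over the class's
        original rootings (the decomposition preserves the score)."""
        rng = make_rng(8080)
        checked = 0
        while checked < 80:
            S, (U,) = random_instance_unrooted(rng, max_trees=1,
                                               max_leaves=10)
            cs = ume.equiv_classes(U, S)
            for c in cs.classes:
                if c.is_plain:
                    continue
                dec = ume.decompose_class(U, S, c, cs.plateau)
                score, _, _ = ume.gnaw(dec.reduced,
                                       list(dec.image_edges.values()),
                                       dec.delta, S)
                want = min(ume.rme_score([U.root_at(e)], S).score
                           for e in c.edges)
                assert score == want
                checked += 1

    def test_gnaw_invariant_to_background_order(self, species,
                                                example_unrooted):
        U = example_unrooted
        cs = ume.equiv_classes(U, species)
        big = max(cs.classes, key=len)
        dec = ume.decompose_class(U, species, big, cs.plateau)
        edges = list(dec.image_edges.values())
        s1, _, _ = ume.gnaw(dec.reduced, edges, dec.delta, species)
        s2, _, _ = ume.gnaw(dec.reduced, edges, dec.delta[::-1], species)
        assert s1 == s2


class TestExact:
    def test_example(self, species, example_unrooted):
        res = ume.exact_ume([example_unrooted], species)
        assert res.score == 4
        assert res.exact

    def test_two_copies_share_episodes(self, species, example_unrooted):
        res = ume.exact_ume([example_unrooted] * 2, species)
        assert res.score == 4

    def test_three_leaf_tree_scores_zero(self):
        S = ume.parse_newick("((a,b),c);", "species")
        U = ume.parse_newick("(a,b,c);", "unrooted")
        assert ume.exact_ume([U], S).score == 0

    def test_matches_naive_oracle(self):
        """exact_ume equals the exhaustive rooting product on 200 random
        instances of up to 4 trees and 10 leaves."""
        rng = make_rng(2024)
        checked = 0
        while checked < 200:
            S, trees = random_instance_unrooted(rng)
            try:
                nv = ume.naive_ume(trees, S, limit=2000)
            except ume.BudgetExceededError:
                continue
            ex = ume.exact_ume(trees, S)
            assert ex.score == nv.score, (S.newick(),
                                          [t.newick() for t in trees])
            checked += 1

    def test_budget_exceeded(self, species, example_unrooted):
        with pytest.raises(ume.BudgetExceededError):
            ume.exact_ume([example_unrooted] * 8, species, budget=100)

    def test_mixed_rooted_and_unrooted(self, species, example_unrooted,
                                       example_g1):
        res = ume.exact_ume([example_unrooted, example_g1], species)
        nv = ume.naive_ume([example_unrooted, example_g1], species)
        assert res.score == nv.score == 4

    def test_k_law(self):
        """The enumeration breadth is the product of class counts, each at
        most 5, and only multi-class trees contribute."""
        rng = make_rng(606)
        for _ in range(60):
            S, trees = random_instance_unrooted(rng, max_trees=3)
            sets = [ume.equiv_classes(U, S) for U in trees]
            k = sum(1 for cs in sets if cs.is_multi)
            breadth = 1
            for cs in sets:
                assert len(cs.classes) in (1, 3, 5)
                breadth *= len(cs.classes)
            assert breadth <= 5 ** k


class TestBoundsAndHeuristic:
    def test_sandwich_on_example(self, species, example_unrooted):
        lb = ume.lower_bound([example_unrooted], species)
        ub = ume.upper_bound([example_unrooted], species)
        assert lb.score <= 4 <= ub.score
        assert ub.score == 4  # the largest class attains the optimum here

    def test_rooted_only_bounds_equal_rme(self, species, example_g1):
        want = ume.rme_score([example_g1], species).score
        assert ume.lower_bound([example_g1], species).score == want
        assert ume.upper_bound([example_g1], species).score == want
        h = ume.heuristic_ume([example_g1], species)
        assert h.score == want and h.exact

    def test_single_class_tree_lower_bound_is_exact(self):
        """For one single-class unrooted tree the lower bound incorporates
        the whole tree, hence equals the exact score."""
        rng = make_rng(1234)
        checked = 0
        while checked < 60:
            S, (U,) = random_instance_unrooted(rng, max_trees=1,
                                               max_leaves=10)
            if ume.equiv_classes(U, S).is_multi:
                continue
            lb = ume.lower_bound([U], S)
            ex = ume.exact_ume([U], S)
            assert lb.score == ex.score
            checked += 1

    def test_sandwich_on_random_instances(self):
        """lower <= exact <= upper; heuristic within [lower, upper] and never
        below exact; heuristic exact whenever the bounds coincide."""
        rng = make_rng(13579)
        checked = 0
        while checked < 120:
            S, trees = random_instance_unrooted(rng)
            try:
                ex = ume.exact_ume(trees, S, budget=2000)
            except ume.BudgetExceededError:
                continue
            lb = ume.lower_bound(trees, S)
            ub = ume.upper_bound(trees, S)
            h = ume.heuristic_ume(trees, S)
            assert lb.score <= ex.score <= ub.score
            assert lb.score <= h.score <= ub.score
            assert h.score >= ex.score
            if lb.score == ub.score:
                assert h.exact and h.score == ex.score
            checked += 1

    def test_heuristic_greedy_path(self):
        """Force the greedy phase (k_budget=0) and check feasibility."""
        rng = make_rng(86420)
        checked = 0
        while checked < 40:
            S, trees = random_instance_unrooted(rng)
            try:
                ex = ume.exact_ume(trees, S, budget=2000)
            except ume.BudgetExceededError:
                continue
            h = ume.heuristic_ume(trees, S, k_budget=0)
            ub = ume.upper_bound(trees, S)
            assert ex.score <= h.score <= ub.score
            checked += 1

    def test_example_heuristic_flags_exact(self, species, example_unrooted):
        h = ume.heuristic_ume([example_unrooted], species)
        assert h.score == 4
        assert h.exact
        assert h.lower is not None and h.upper is not None
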