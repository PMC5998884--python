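"""lca mapping, duplication cost, edge types, plateau and node roles."""
import random

import pytest

import ume
from ume.reconcile import (CONDITIONAL, DOUBLE, EMPTY, SINGLE,
                           SUPER_DUPLICATION, SUPER_SPECIATION)

from conftest import make_rng, random_instance_unrooted


class TestLcaMapping:
    def test_leaf_maps_to_species_leaf(self, species):
        G = ume.parse_newick("(a,b);", "rooted")
        m = ume.lca_map(G, species)
        leaf_a = next(l for l in G.leaves if l.label == "a")
        assert m.image(leaf_a) is species.leaf_by_label["a"]
        assert not m.is_duplication(leaf_a)

    def test_species_restriction_has_no_duplications(self, species):
        G = ume.parse_newick("((a,b),(c,d));", "rooted")
        assert ume.dup_cost(G, species) == 0

    def test_unknown_species_errors(self, species):
        G = ume.parse_newick("(a,zz);", "rooted")
        with pytest.raises(ume.TreeError):
            ume.lca_map(G, species)

    def test_g1_mapping_and_cost(self, species, example_g1):
        """The empty-edge rooting has two nested duplications mapping to the
        {a,b,c,d} node plus one duplication in each doubled subtree."""
        m = ume.lca_map(example_g1, species)
        by_canon = {}
        for n in example_g1.postorder():
            if not n.is_leaf:
                by_canon[ume.canonical_rooted(n)] = n
        abcd = species.node_by_cluster[frozenset("abcd")]
        assert m.image(by_canon["((a,b),b)"]) is species.node_by_cluster[
            frozenset("ab")]
        assert m.image(by_canon["((c,d),d)"]) is species.node_by_cluster[
            frozenset("cd")]
        assert m.image(by_canon["(((a,b),b),((c,d),d))"]) is abcd
        assert not m.is_duplication(by_canon["(((a,b),b),((c,d),d))"])
        above = ume.canonical_rooted(
            ume.parse_newick("(c,(((a,b),b),((c,d),d)));", "rooted"))
        assert m.image(by_canon[above]) is abcd
        assert m.is_duplication(by_canon[above])
        assert ume.dup_cost(example_g1, species) == 4

    def test_simple_duplication(self):
        S = ume.parse_newick("((a,b),c);", "species")
        assert ume.dup_cost(ume.parse_newick("((a,a),b);", "rooted"), S) == 1


class TestEdgeMaps:
    def test_leaf_direction_maps_to_species_leaf(self, species,
                                                 example_unrooted):
        U = example_unrooted
        em = ume.edge_maps(U, species)
        for v in U.leaves:
            (u,) = U.neighbors(v)
            assert em.image(u, v) is species.leaf_by_label[U.labels[v]]

    def test_edge_images_consistent_with_rootings(self, species,
                                                  example_unrooted):
        U = example_unrooted
        em = ume.edge_maps(U, species)
        for u, v in U.edges():
            G = U.root_at((u, v))
            m = ume.lca_map(G, species)
            assert m.image(G.root) is species.lca(em.image(u, v),
                                                  em.image(v, u))

    def test_effective_top_for_restricted_family(self):
        S = ume.parse_newick("(((a,b),(c,d)),e);", "species")
        U = ume.parse_newick("((a,b),(a,b));", "unrooted")
        em = ume.edge_maps(U, S)
        assert S.cluster(em.top) == frozenset("ab")


class TestEdgeTypes:
    def test_example_edge_types(self, species, example_unrooted):
        U = example_unrooted
        info = ume.plateau(U, species)
        leaf = {U.labels[v]: v for v in U.leaves if U.labels[v] in "de"}
        # the edge from leaf e into the tree is the unique empty edge
        (ve,) = U.neighbors(leaf["e"])
        e_edge = (min(leaf["e"], ve), max(leaf["e"], ve))
        assert info.edge_types[e_edge] == EMPTY
        assert info.empty_edge == e_edge
        (vd,) = U.neighbors(leaf["d"])
        d_edge = (min(leaf["d"], vd), max(leaf["d"], vd))
        assert info.edge_types[d_edge] == SINGLE

    def test_double_edge_quartet(self):
        S = ume.parse_newick("(a,b);", "species")
        U = ume.parse_newick("((a,b),(a,b));", "unrooted")
        info = ume.plateau(U, S)
        central = [e for e in U.edges()
                   if not U.is_leaf(e[0]) and not U.is_leaf(e[1])]
        assert info.edge_types[central[0]] == DOUBLE
        assert info.edges == frozenset(central)

    def test_three_leaf_plateau(self):
        S = ume.parse_newick("((a,b),c);", "species")
        U = ume.parse_newick("(a,b,c);", "unrooted")
        info = ume.plateau(U, S)
        assert info.min_cost == 0
        c_leaf = next(v for v in U.leaves if U.labels[v] == "c")
        assert info.edges == frozenset(
            {(min(c_leaf, w), max(c_leaf, w)) for w in U.neighbors(c_leaf)})


class TestPlateauProperties:
    def test_example_plateau_size(self, species, example_unrooted):
        info = ume.plateau(example_unrooted, species)
        assert len(info.edges) == 5
        assert info.min_cost == 4
        assert len(info.s2_stars) == 1

    def test_plateau_matches_brute_force_and_structure(self):
        """On random instances: plateau = argmin over all rootings; it is
        connected; one empty edge XOR at least one double edge; node roles
        hold in every optimal rooting."""
        rng = make_rng(20260901)
        for _ in range(200):
            S, (U,) = random_instance_unrooted(rng, max_trees=1,
                                               max_leaves=12)
            info = ume.plateau(U, S)
            costs = {e: ume.dup_cost(U.root_at(e), S) for e in U.edges()}
            mc = min(costs.values())
            assert info.min_cost == mc
            assert info.edges == frozenset(
                e for e, c in costs.items() if c == mc)
            # connectivity of U*
            adj = {}
            for u, v in info.edges:
                adj.setdefault(u, []).append(v)
                adj.setdefault(v, []).append(u)
            start = info.nodes[0]
            seen, stack = {start}, [start]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            assert seen == set(info.nodes)
            # exactly one empty edge XOR >= 1 double edge in the plateau
            n_empty = sum(1 for e in info.edges
                          if info.edge_types[e] == EMPTY)
            n_double = sum(1 for e in info.edges
                           if info.edge_types[e] == DOUBLE)
            assert (n_empty == 1) != (n_double >= 1)
            # role checks against every plateau rooting
            for e in info.edges:
                G = U.root_at(e)
                m = ume.lca_map(G, S)
                for n in G.postorder():
                    if n.is_leaf or n.source is None:
                        continue
                    role = info.roles.get(n.source)
                    if role == SUPER_DUPLICATION:
                        assert m.is_duplication(n)
                    elif role == SUPER_SPECIATION:
                        assert not m.is_duplication(n)

    def test_conditional_nodes_lemma(self):
        """A node on the empty edge is a speciation in the empty-edge rooting
        iff it is a plateau leaf."""
        rng = make_rng(42)
        checked = 0
        while checked < 80:
            S, (U,) = random_instance_unrooted(rng, max_trees=1,
                                               max_leaves=12)
            info = ume.plateau(U, S)
            if info.empty_edge is None:
                continue
            G = U.root_at(info.empty_edge)
            m = ume.lca_map(G, S)
            for n in G.root.children:
                if n.is_leaf:
                    continue
                is_plateau_leaf = info.plateau_degree(n.source) == 1
                assert (not m.is_duplication(n)) == is_plateau_leaf
            checked += 1

    def test_plateau_roles_partition(self, species, example_unrooted):
        info = ume.plateau(example_unrooted, species)
        for v in info.leaf_nodes:
            assert info.roles[v] == SUPER_SPECIATION
        for v in info.internal_nodes:
            assert info.roles[v] in (SUPER_DUPLICATION, CONDITIONAL)
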