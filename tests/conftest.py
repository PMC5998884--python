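"""Shared fixtures: the worked example trees and random-instance generators."""
import random

import pytest

import ume
from ume.simulate import (random_rooted_gene_tree, random_species_tree,
                          random_unrooted_gene_tree)

# The five-species worked example used throughout: an unrooted nine-leaf gene
# tree whose plateau has five edges and splits into three ~-classes.
SPECIES_NEWICK = "(((a,b),(c,d)),e);"
UNROOTED_NEWICK = "(d,e,(c,(((a,b),b),((c,d),d))));"
G1_NEWICK = "(e,(d,(c,(((a,b),b),((c,d),d)))));"  # empty-edge rooting
DLS_EXAMPLE = "(((((a,a)+,b-)~,(c,d-)~)~,(ab-,(c-,d)~)~)+,e)~"


@pytest.fixture(scope="session")
def species():
    return ume.parse_newick(SPECIES_NEWICK, "species")


@pytest.fixture(scope="session")
def example_unrooted():
    return ume.parse_newick(UNROOTED_NEWICK, "unrooted")


@pytest.fixture(scope="session")
def example_g1():
    return ume.parse_newick(G1_NEWICK, "rooted")


def make_rng(seed: int) -> random.Random:
    return random.Random(seed)


def random_instance_unrooted(rng, max_trees=4, max_leaves=10,
                             min_species=2, max_species=6):
    """A random species tree plus a set of random unrooted gene trees."""
    S = random_species_tree(rng, rng.randint(min_species, max_species))
    trees = [random_unrooted_gene_tree(rng, S, rng.randint(3, max_leaves))
             for _ in range(rng.randint(1, max_trees))]
    return S, trees


def random_instance_rooted(rng, max_trees=4, max_leaves=5, max_dups=8,
                           min_species=2, max_species=5):
    """A random rooted instance with at most ``max_dups`` duplications."""
    while True:
        S = random_species_tree(rng, rng.randint(min_species, max_species))
        trees = [random_rooted_gene_tree(rng, S, rng.randint(2, max_leaves))
                 for _ in range(rng.randint(1, max_trees))]
        if sum(ume.lca_map(t, S).dup_count for t in trees) <= max_dups:
            return S, trees
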