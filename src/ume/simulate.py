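"""Synthetic gene-family generator: duplication-loss scenarios on a species
tree, with optional injected multi-family duplication episodes.

Families evolve top-down along the species tree: a lineage arriving at a
species node may duplicate (per-arrival Bernoulli; an *episode* node forces
one duplication in every participating family), then either speciates into
the node's children -- each child lineage surviving with probability
``1 - loss_prob`` -- or terminates at a leaf as a gene sequence.  The output
of each family is the full DLS scenario, the extracted rooted gene tree, and
its unrooted version; families whose gene tree is too small to unroot are
resampled.

The module also provides the random tree generators used by the test suite
and the acceptance script.
"""
from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .dls import DLSNode, DLSTree, DUP, GENE, LOSS, SPEC, gt
from .trees import (RootedGeneTree, SpeciesTree, TreeError, TreeNode,
                    UnrootedGeneTree)

__all__ = [
    "SimParams", "SimulatedFamily", "simulate", "unroot",
    "random_species_tree", "random_rooted_gene_tree", "random_unrooted_gene_tree",
]


@dataclass
class SimParams:
    """Simulation settings.

    ``episodes`` lists (species cluster, participation probability) pairs: in
    a participating family the lineage first reaching that species node is
    forced to duplicate there once.  Defaults are deliberate: 0.1 / 0.1 for
    the per-branch duplication and per-lineage loss probabilities give gene
    trees that mostly resemble the species tree with occasional small
    paralogous clades, the regime the episode solvers target.
    """
    species_tree: SpeciesTree
    families: int = 100
    dup_prob: float = 0.1
    loss_prob: float = 0.1
    episodes: Sequence[Tuple[frozenset, float]] = ()
    seed: Optional[int] = None
    max_retries: int = 1000

    def __post_init__(self):
        for p in (self.dup_prob, self.loss_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for cluster, p in self.episodes:
            if cluster not in self.species_tree.node_by_cluster:
                raise ValueError(
                    f"episode cluster {sorted(cluster)} is not a species-tree "
                    "cluster")
            if not 0.0 <= p <= 1.0:
                raise ValueError("participation probability must lie in [0, 1]")


@dataclass
class SimulatedFamily:
    scenario: DLSTree
    rooted: RootedGeneTree
    unrooted: UnrootedGeneTree


_MAX_DUP_EVENTS = 10_000  # safety valve against pathological rate settings


def _one_family(params: SimParams, rng: random.Random) -> DLSTree:
    S = params.species_tree
    forced = {S.node_by_cluster[c].id
              for c, p in params.episodes if rng.random() < p}
    events = 0

    def arrive(v: TreeNode) -> DLSNode:
        nonlocal events
        if v.id in forced:
            forced.discard(v.id)
            do_dup = True
        else:
            do_dup = rng.random() < params.dup_prob
        if do_dup:
            events += 1
            if events > _MAX_DUP_EVENTS:
                raise RuntimeError("runaway duplication chain; lower dup_prob")
            return DLSNode(kind=DUP, species=S.cluster(v),
                           children=[arrive(v), arrive(v)])
        if v.is_leaf:
            return DLSNode(kind=GENE, species=S.cluster(v), label=v.label)
        kids = []
        for c in v.children:
            if rng.random() < params.loss_prob:
                kids.append(DLSNode(kind=LOSS, species=S.cluster(c)))
            else:
                kids.append(arrive(c))
        return DLSNode(kind=SPEC, species=S.cluster(v), children=kids)

    return DLSTree(arrive(S.root))


def simulate(params: SimParams) -> List[SimulatedFamily]:
    """Generate ``params.families`` families; seeded and reproducible.

    Every emitted gene tree has at least 3 leaves (so an unrooted version
    exists); a family falling below that is resampled, and persistent failure
    (e.g. loss rate 1) raises after ``max_retries`` attempts.
    """
    rng = random.Random(params.seed)
    out: List[SimulatedFamily] = []
    for _ in range(params.families):
        for _attempt in range(params.max_retries):
            scenario = _one_family(params, rng)
            if len(scenario.gene_leaves) >= 3:
                rooted = gt(scenario)
                out.append(SimulatedFamily(
                    scenario=scenario, rooted=rooted, unrooted=unroot(rooted)))
                break
        else:
            raise RuntimeError(
                "could not generate a non-trivial family within "
                f"{params.max_retries} attempts (rates too extreme?)")
    return out


def unroot(tree: RootedGeneTree) -> UnrootedGeneTree:
    """Dissolve the root of a rooted gene tree (requires >= 3 leaves)."""
    if len(tree.leaves) < 3:
        raise TreeError("cannot unroot a gene tree with fewer than 3 leaves")
    return UnrootedGeneTree.from_rooted(tree)


# ---------------------------------------------------------------------------
# random tree generators (adversarial fixtures for property tests)
# ---------------------------------------------------------------------------

def random_species_tree(rng: random.Random, n_species: int,
                        labels: Optional[Sequence[str]] = None) -> SpeciesTree:
    """Uniform-ish random binary species tree by random pair merging."""
    if labels is None:
        if n_species > 26:
            raise ValueError("default labels support up to 26 species")
        labels = [chr(ord("a") + i) for i in range(n_species)]
    nodes = [TreeNode(label=l) for l in labels]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append(TreeNode(children=[a, b]))
    return SpeciesTree(nodes[0])


def random_rooted_gene_tree(rng: random.Random, species: SpeciesTree,
                            n_leaves: int) -> RootedGeneTree:
    """Random binary topology over leaves sampled (with repeats) from S."""
    pool = [l.label for l in species.leaves]
    nodes = [TreeNode(label=rng.choice(pool)) for _ in range(n_leaves)]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append(TreeNode(children=[a, b]))
    return RootedGeneTree(nodes[0])


def random_unrooted_gene_tree(rng: random.Random, species: SpeciesTree,
                              n_leaves: int) -> UnrootedGeneTree:
    if n_leaves < 3:
        raise ValueError("unrooted trees need at least 3 leaves")
    return unroot(random_rooted_gene_tree(rng, species, n_leaves))
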