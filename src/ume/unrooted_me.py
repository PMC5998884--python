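"""Minimum-episodes solvers for unrooted (and mixed) gene-tree collections.

The minimum-episodes score of a collection is the smallest total number of
duplication episodes over all scenarios that keep every tree's duplication
count minimal; for an unrooted tree that means minimising over its plateau
rootings.  The solvers here:

* ``naive_ume``  -- exhaustive product over plateau rootings (the oracle);
* ``exact_ume``  -- enumerates the product of ~-classes (at most 5 per tree),
  decomposing each complex class into detached rooted trees plus a reduced
  unrooted tree whose best rooting is found by ``gnaw``;
* ``lower_bound`` / ``upper_bound`` -- linear-time sandwich bounds;
* ``heuristic_ume`` -- bounds first (equal bounds certify exactness), exact
  enumeration when the number of multi-class trees is small, otherwise a
  greedy that repeatedly commits the tree/class pair with the smallest
  incremental episode cost.

All solvers return a :class:`UMEResult` whose episodes and per-node counts
come from a final rooted minimum-episodes run over the chosen rootings.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

from .decompose import DecompositionResult, EquivClass, EquivClassSet, \
    decompose_class, equiv_classes
from .reconcile import lca_map, plateau
from .rooted_me import Episode, MEScoreRooted, rme_score
from .trees import (Edge, RootedGeneTree, SpeciesTree,
                    UnrootedGeneTree)

__all__ = [
    "BudgetExceededError", "TreeDecision", "UMEResult",
    "gnaw", "naive_ume", "exact_ume",
    "lower_bound", "upper_bound", "heuristic_ume",
]

GeneTree = Union[RootedGeneTree, UnrootedGeneTree]


class BudgetExceededError(RuntimeError):
    """The enumeration would exceed its combination budget; use the heuristic."""


@dataclass
class TreeDecision:
    """How one input tree entered the final scoring.

    kind: ``rooted`` (passed through), ``plain`` / ``complex`` (class chosen,
    ``edge`` is the rooting edge in the *original* unrooted tree), or
    ``non-plateau`` (only the subtrees hanging off the plateau were kept --
    lower bound on multi-class trees).
    """
    kind: str
    class_key: Optional[str] = None
    edge: Optional[Edge] = None


@dataclass
class UMEResult:
    score: int
    method: str
    exact: bool
    decisions: Dict[int, TreeDecision]
    rooted: MEScoreRooted
    lower: Optional[int] = None
    upper: Optional[int] = None

    @property
    def episodes(self) -> List[Episode]:
        return self.rooted.episodes

    @property
    def lambdas(self) -> Dict[int, int]:
        return self.rooted.lambdas


# ---------------------------------------------------------------------------
# preparation
# ---------------------------------------------------------------------------

class _Entry:
    """Per-input-tree cache of plateau, classes and decompositions."""

    def __init__(self, index: int, tree: GeneTree, species: SpeciesTree,
                 species_of):
        self.index = index
        self.species = species
        self.species_of = species_of
        if isinstance(tree, UnrootedGeneTree):
            self.kind = "unrooted"
            self.U = tree
            self.info = plateau(tree, species, species_of)
            self.classes = equiv_classes(tree, species, self.info, species_of)
            self._dec: Dict[str, DecompositionResult] = {}
            self.root_is_dup = False
        else:
            self.kind = "rooted"
            self.tree = tree
            mapping = lca_map(tree, species, species_of)
            self.root_is_dup = (not tree.root.is_leaf
                                and mapping.is_duplication(tree.root))

    def decomp(self, cls: EquivClass) -> DecompositionResult:
        if cls.key not in self._dec:
            self._dec[cls.key] = decompose_class(
                self.U, self.species, cls, self.info, self.species_of)
        return self._dec[cls.key]


def _prepare(trees: Sequence[GeneTree], species: SpeciesTree,
             species_of) -> Tuple[List[_Entry], List[_Entry]]:
    entries = [_Entry(i, t, species, species_of)
               for i, t in enumerate(trees)]
    rooted = [e for e in entries if e.kind == "rooted"]
    unrooted = [e for e in entries if e.kind == "unrooted"]
    return rooted, unrooted


def _orig_edge(dec: DecompositionResult, reduced_edge: Edge) -> Edge:
    inv = {img: orig for orig, img in dec.image_edges.items()}
    return inv[reduced_edge]


# ---------------------------------------------------------------------------
# gnaw
# ---------------------------------------------------------------------------

def gnaw(reduced: UnrootedGeneTree, class_edges: Sequence[Edge],
         background: Sequence[RootedGeneTree], species: SpeciesTree,
         species_of=None) -> Tuple[int, Dict[Edge, int], Edge]:
    """Minimum episode score over the rootings of a complex class.

    Returns ``(min score, per-edge scores, best edge)`` where each edge score
    is the full rooted minimum-episodes score of the background together with
    the reduced tree rooted on that edge.  Ties break to the smallest edge.
    """
    per_edge: Dict[Edge, int] = {}
    best_edge: Optional[Edge] = None
    best = None
    for e in sorted(class_edges):
        res = rme_score(list(background) + [reduced.root_at(e)],
                        species, species_of)
        per_edge[e] = res.score
        if best is None or res.score < best:
            best, best_edge = res.score, e
    if best_edge is None:
        raise ValueError("gnaw called with no class edges")
    return best, per_edge, best_edge


def _gnaw_incremental(reduced: UnrootedGeneTree, class_edges: Sequence[Edge],
                      base_lambdas: Dict[int, int], species: SpeciesTree,
                      extra_trees: Sequence[RootedGeneTree] = (),
                      species_of=None) -> Tuple[Edge, MEScoreRooted]:
    """Best class rooting against a fixed background episode capacity.

    Scores only the episodes added beyond ``base_lambdas``; linear per edge.
    """
    best_edge = None
    best_res = None
    for e in sorted(class_edges):
        res = rme_score(list(extra_trees) + [reduced.root_at(e)],
                        species, species_of, base_lambdas=base_lambdas)
        if best_res is None or res.score < best_res.score:
            best_edge, best_res = e, res
    assert best_edge is not None and best_res is not None
    return best_edge, best_res


# ---------------------------------------------------------------------------
# naive oracle
# ---------------------------------------------------------------------------

def naive_ume(trees: Sequence[GeneTree], species: SpeciesTree,
              species_of=None, limit: int = 10_000) -> UMEResult:
    """Exhaustive minimum over every combination of plateau rootings."""
    rooted, unrooted = _prepare(trees, species, species_of)
    total = 1
    for e in unrooted:
        total *= len(e.info.edges)
        if total > limit:
            raise BudgetExceededError(
                f"naive enumeration exceeds {limit} rooting combinations")
    background = [e.tree for e in rooted]
    options = [e.info.sorted_edges() for e in unrooted]
    best = None
    best_combo = None
    for combo in itertools.product(*options):
        res = rme_score(background + [en.U.root_at(edge)
                                      for en, edge in zip(unrooted, combo)],
                        species, species_of)
        if best is None or res.score < best.score:
            best, best_combo = res, combo
    assert best is not None
    decisions = {e.index: TreeDecision(kind="rooted") for e in rooted}
    for en, edge in zip(unrooted, best_combo or ()):
        decisions[en.index] = TreeDecision(kind="plateau-rooting", edge=edge)
    return UMEResult(score=best.score, method="naive", exact=True,
                     decisions=decisions, rooted=best)


# ---------------------------------------------------------------------------
# exact class enumeration
# ---------------------------------------------------------------------------

def _score_combo(background: List[RootedGeneTree],
                 complexes: List[Tuple[_Entry, EquivClass,
                                       DecompositionResult]],
                 species: SpeciesTree, species_of,
                 bg_root_dup: bool, budget: int
                 ) -> Tuple[MEScoreRooted, Dict[int, Edge]]:
    """Score one element of the class product, minimising over rootings.

    With at most one complex class, or a background in which every root is a
    speciation, the per-tree best rootings are independent (the reduced
    trees' duplications interact only through shared root-level episodes), so
    one gnaw per tree followed by a joint scoring run is exact.  Otherwise
    the full product of class edges is evaluated.
    """
    if not complexes:
        return rme_score(background, species, species_of), {}
    chosen_edges: Dict[int, Edge] = {}
    if len(complexes) == 1 or not bg_root_dup:
        rootings = []
        for entry, cls, dec in complexes:
            _, _, best_e = gnaw(dec.reduced, list(dec.image_edges.values()),
                                background, species, species_of)
            chosen_edges[entry.index] = _orig_edge(dec, best_e)
            rootings.append(dec.reduced.root_at(best_e))
        return rme_score(background + rootings, species, species_of), \
            chosen_edges
    # definitional fallback: product over class edges
    options = [sorted(dec.image_edges.values()) for _, _, dec in complexes]
    total = 1
    for opt in options:
        total *= len(opt)
        if total > budget:
            raise BudgetExceededError(
                "edge-product evaluation exceeds the combination budget")
    best = None
    best_combo = None
    for combo in itertools.product(*options):
        res = rme_score(background
                        + [dec.reduced.root_at(e)
                           for (entry, cls, dec), e in zip(complexes, combo)],
                        species, species_of)
        if best is None or res.score < best.score:
            best, best_combo = res, combo
    assert best is not None and best_combo is not None
    for (entry, cls, dec), e in zip(complexes, best_combo):
        chosen_edges[entry.index] = _orig_edge(dec, e)
    return best, chosen_edges


def exact_ume(trees: Sequence[GeneTree], species: SpeciesTree,
              species_of=None, budget: int = 100_000) -> UMEResult:
    """Exact minimum-episodes score via ~-class enumeration.

    The number of evaluated combinations is the product of per-tree class
    counts (at most 5 each; 1 for every tree without an S2 star), capped by
    ``budget``.
    """
    rooted, unrooted = _prepare(trees, species, species_of)
    total = 1
    for e in unrooted:
        total *= len(e.classes.classes)
        if total > budget:
            raise BudgetExceededError(
                f"class enumeration exceeds {budget} combinations; "
                "use heuristic_ume")
    rooted_bg = [e.tree for e in rooted]
    bg_root_dup = any(e.root_is_dup for e in rooted)

    best: Optional[MEScoreRooted] = None
    best_decisions: Optional[Dict[int, TreeDecision]] = None
    for choice in itertools.product(*[e.classes.classes for e in unrooted]):
        background = list(rooted_bg)
        decisions = {e.index: TreeDecision(kind="rooted") for e in rooted}
        complexes: List[Tuple[_Entry, EquivClass, DecompositionResult]] = []
        for entry, cls in zip(unrooted, choice):
            dec = entry.decomp(cls)
            if cls.is_plain:
                background.append(dec.rooting)
                decisions[entry.index] = TreeDecision(
                    kind="plain", class_key=cls.key,
                    edge=entry.info.empty_edge)
            else:
                background.extend(dec.delta)
                complexes.append((entry, cls, dec))
        res, edges = _score_combo(background, complexes, species, species_of,
                                  bg_root_dup, budget)
        for entry, cls, dec in complexes:
            decisions[entry.index] = TreeDecision(
                kind="complex", class_key=cls.key,
                edge=edges[entry.index])
        if best is None or res.score < best.score:
            best, best_decisions = res, decisions
    assert best is not None and best_decisions is not None
    return UMEResult(score=best.score, method="exact", exact=True,
                     decisions=best_decisions, rooted=best)


# ---------------------------------------------------------------------------
# linear-time bounds
# ---------------------------------------------------------------------------

def _hanging_subtrees(entry: _Entry) -> List[RootedGeneTree]:
    """Rooted subtrees hanging off the plateau leaves (plateau dups dropped)."""
    out = []
    info = entry.info
    for v in info.leaf_nodes:
        (pe,) = [e for e in info.edges if v in e]
        u = pe[0] if pe[1] == v else pe[1]
        out.append(RootedGeneTree(entry.U.subtree(v, away_from=u)))
    return out


def lower_bound(trees: Sequence[GeneTree], species: SpeciesTree,
                species_of=None) -> UMEResult:
    """Lower bound on the exact score, linear in the input.

    Multi-class trees contribute only the duplications outside their plateau
    (the subtrees hanging off plateau leaves are kept; plateau duplications
    are discarded, which can only lower the optimum).  Single-class trees are
    incorporated in full through their one class.
    """
    rooted, unrooted = _prepare(trees, species, species_of)
    background = [e.tree for e in rooted]
    decisions = {e.index: TreeDecision(kind="rooted") for e in rooted}
    pending: List[Tuple[_Entry, DecompositionResult]] = []
    for entry in unrooted:
        classes = entry.classes.classes
        if len(classes) == 1:
            cls = classes[0]
            dec = entry.decomp(cls)
            if cls.is_plain:
                background.append(dec.rooting)
                decisions[entry.index] = TreeDecision(
                    kind="plain", class_key=cls.key,
                    edge=entry.info.empty_edge)
            else:
                background.extend(dec.delta)
                pending.append((entry, dec))
        else:
            background.extend(_hanging_subtrees(entry))
            decisions[entry.index] = TreeDecision(kind="non-plateau")
    base = rme_score(background, species, species_of)
    lambdas = base.lambdas
    chosen: List[RootedGeneTree] = []
    for entry, dec in pending:
        best_e, res = _gnaw_incremental(
            dec.reduced, list(dec.image_edges.values()), lambdas, species,
            species_of=species_of)
        lambdas = res.lambdas
        chosen.append(dec.reduced.root_at(best_e))
        decisions[entry.index] = TreeDecision(
            kind="complex", class_key=dec.cls.key,
            edge=_orig_edge(dec, best_e))
    final = rme_score(background + chosen, species, species_of)
    return UMEResult(score=final.score, method="lower", exact=False,
                     decisions=decisions, rooted=final, lower=final.score)


def upper_bound(trees: Sequence[GeneTree], species: SpeciesTree,
                species_of=None) -> UMEResult:
    """Upper bound: one feasible class combination, scored exactly.

    Each unrooted tree contributes its largest class (ties: plain first, then
    class order); complex classes are rooted by gnaw against the accumulated
    background.
    """
    rooted, unrooted = _prepare(trees, species, species_of)
    background = [e.tree for e in rooted]
    decisions = {e.index: TreeDecision(kind="rooted") for e in rooted}
    pending: List[Tuple[_Entry, DecompositionResult]] = []
    for entry in unrooted:
        classes = entry.classes.classes
        i, cls = min(enumerate(classes), key=lambda ic: (-len(ic[1]), ic[0]))
        dec = entry.decomp(cls)
        if cls.is_plain:
            background.append(dec.rooting)
            decisions[entry.index] = TreeDecision(
                kind="plain", class_key=cls.key, edge=entry.info.empty_edge)
        else:
            background.extend(dec.delta)
            pending.append((entry, dec))
    base = rme_score(background, species, species_of)
    lambdas = base.lambdas
    chosen: List[RootedGeneTree] = []
    for entry, dec in pending:
        best_e, res = _gnaw_incremental(
            dec.reduced, list(dec.image_edges.values()), lambdas, species,
            species_of=species_of)
        lambdas = res.lambdas
        chosen.append(dec.reduced.root_at(best_e))
        decisions[entry.index] = TreeDecision(
            kind="complex", class_key=dec.cls.key,
            edge=_orig_edge(dec, best_e))
    final = rme_score(background + chosen, species, species_of)
    return UMEResult(score=final.score, method="upper", exact=False,
                     decisions=decisions, rooted=final, upper=final.score)


# ---------------------------------------------------------------------------
# heuristic
# ---------------------------------------------------------------------------

def heuristic_ume(trees: Sequence[GeneTree], species: SpeciesTree,
                  species_of=None, k_budget: int = 7,
                  budget: int = 100_000) -> UMEResult:
    """Bounds-first heuristic; exact whenever it can certify it.

    Phase 1 computes the sandwich bounds; equal bounds prove the upper-bound
    combination optimal.  Phase 2 runs the exact class enumeration when the
    number of multi-class trees k is small (the enumeration is <= 5^k), and
    otherwise greedily commits, among all remaining (tree, class) pairs, the
    one whose best rooting adds the fewest episodes to the current
    background.  The result is never worse than the upper bound.
    """
    lb = lower_bound(trees, species, species_of)
    ub = upper_bound(trees, species, species_of)
    if lb.score == ub.score:
        return UMEResult(score=ub.score, method="heuristic", exact=True,
                         decisions=ub.decisions, rooted=ub.rooted,
                         lower=lb.score, upper=ub.score)

    rooted, unrooted = _prepare(trees, species, species_of)
    k = sum(1 for e in unrooted if e.classes.is_multi)
    total = 1
    for e in unrooted:
        total *= len(e.classes.classes)
    if k <= k_budget and total <= budget:
        res = exact_ume(trees, species, species_of, budget)
        return UMEResult(score=res.score, method="heuristic", exact=True,
                         decisions=res.decisions, rooted=res.rooted,
                         lower=lb.score, upper=ub.score)

    background = [e.tree for e in rooted]
    decisions = {e.index: TreeDecision(kind="rooted") for e in rooted}
    lambdas = rme_score(background, species, species_of).lambdas
    pending = list(unrooted)
    committed: List[RootedGeneTree] = []
    while pending:
        best_key = None
        best_pick = None
        for pos, entry in enumerate(pending):
            for ci, cls in enumerate(entry.classes.classes):
                dec = entry.decomp(cls)
                if cls.is_plain:
                    res = rme_score([dec.rooting], species, species_of,
                                    base_lambdas=lambdas)
                    pick = (entry, cls, dec, [dec.rooting],
                            entry.info.empty_edge, res)
                else:
                    best_e, res = _gnaw_incremental(
                        dec.reduced, list(dec.image_edges.values()), lambdas,
                        species, extra_trees=dec.delta,
                        species_of=species_of)
                    pick = (entry, cls, dec,
                            list(dec.delta) + [dec.reduced.root_at(best_e)],
                            _orig_edge(dec, best_e), res)
                key = (res.score, entry.index, ci)
                if best_key is None or key < best_key:
                    best_key, best_pick = key, pick
        entry, cls, dec, cand_trees, edge, res = best_pick
        lambdas = res.lambdas
        committed.extend(cand_trees)
        pending.remove(entry)
        decisions[entry.index] = TreeDecision(
            kind=cls.kind, class_key=cls.key, edge=edge)
    greedy = rme_score(background + committed, species, species_of)
    if greedy.score <= ub.score:
        final, final_dec = greedy, decisions
    else:
        final, final_dec = ub.rooted, ub.decisions
    return UMEResult(score=final.score, method="heuristic",
                     exact=(final.score == lb.score),
                     decisions=final_dec, rooted=final,
                     lower=lb.score, upper=ub.score)
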