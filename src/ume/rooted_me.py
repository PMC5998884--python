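"""Minimum-episodes scoring for rooted gene trees.

Every duplication d in a reconciled gene tree may be placed anywhere on the
species-tree interval I(d) = [M(d), s]: the bottom is its lca image, the top
s is the child (towards d) of the image of the lowest speciation strictly
above d, or the species-tree root when no such speciation exists.  An
assignment places every duplication in a slot (species node, level) subject
to interval feasibility and monotonicity: an ancestor duplication must sit in
a strictly larger slot than its descendants (slots are ordered by species
node along the root path, then by level).

The score is sum over species nodes s of lambda(s), where lambda(s) is the
maximum over trees of the longest chain of pairwise-comparable duplications
of that tree placed at s -- duplications of different trees (and incomparable
duplications of one tree) at the same (node, level) share an episode.

``rme_score`` is a greedy bottom-up solver: at each species node it
force-assigns the duplications whose interval tops end there, fixes
lambda(s), then pulls any still-unassigned duplication whose interval covers
s into a free level <= lambda(s) (which can never worsen the final score).
``brute_force_rme`` is the exhaustive oracle used to guard optimality.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .reconcile import LcaMapping, lca_map
from .trees import RootedGeneTree, SpeciesTree, TreeNode

__all__ = [
    "DupInterval", "intervals",
    "Episode", "MEScoreRooted",
    "rme_score", "brute_force_rme",
]


@dataclass
class DupInterval:
    """Allowed species-tree placements [bottom, top] of one duplication."""
    tree_index: int
    node: TreeNode        # the duplication node in the gene tree
    bottom: TreeNode      # M(d)
    top: TreeNode         # child of M(lowest speciation above d), or root(S)


def intervals(tree: RootedGeneTree, species: SpeciesTree,
              species_of: Optional[Callable[[str], str]] = None,
              mapping: Optional[LcaMapping] = None,
              tree_index: int = 0) -> List[DupInterval]:
    """One interval per duplication, in a single top-down pass."""
    mapping = mapping or lca_map(tree, species, species_of)
    out: List[DupInterval] = []
    # (node, lowest speciation ancestor image or None)
    stack: List[Tuple[TreeNode, Optional[TreeNode]]] = [(tree.root, None)]
    while stack:
        n, spec_img = stack.pop()
        if not n.is_leaf:
            if mapping.is_duplication(n):
                bottom = mapping.image(n)
                if spec_img is None:
                    top = species.root
                else:
                    # the child of the speciation image lying towards d
                    top = next(c for c in spec_img.children
                               if species.leq(bottom, c))
                out.append(DupInterval(tree_index=tree_index, node=n,
                                       bottom=bottom, top=top))
                below = spec_img
            else:
                below = mapping.image(n)
            for c in n.children:
                stack.append((c, below))
    out.sort(key=lambda d: d.node.id)
    return out


@dataclass
class Episode:
    """One duplication episode: a (species node, level) slot and its members."""
    species_node: TreeNode
    level: int
    members: List[Tuple[int, TreeNode]]  # (tree index, duplication node)


@dataclass
class MEScoreRooted:
    """Result of a rooted minimum-episodes computation.

    ``lambdas`` holds the effective per-species-node episode capacity after
    the run (including any pre-existing ``base_lambdas`` capacity); ``score``
    counts only the episodes added beyond that base.
    """
    score: int
    species: SpeciesTree
    lambdas: Dict[int, int]
    episodes: List[Episode]
    assignment: Dict[Tuple[int, int], Tuple[int, int]]  # (tree,node)->(s,level)


class _Dup:
    __slots__ = ("idx", "tree", "node", "bottom", "top", "desc",
                 "slot")

    def __init__(self, idx: int, iv: DupInterval):
        self.idx = idx
        self.tree = iv.tree_index
        self.node = iv.node
        self.bottom = iv.bottom
        self.top = iv.top
        self.desc: List[int] = []   # indices of same-tree descendant dups
        self.slot: Optional[Tuple[int, int]] = None  # (species id, level)


def _collect_dups(trees: Sequence[RootedGeneTree], species: SpeciesTree,
                  species_of) -> List[_Dup]:
    dups: List[_Dup] = []
    for t_idx, tree in enumerate(trees):
        mapping = lca_map(tree, species, species_of)
        ivs = intervals(tree, species, mapping=mapping, tree_index=t_idx)
        base = len(dups)
        for k, iv in enumerate(ivs):
            dups.append(_Dup(base + k, iv))
        # ancestor sets within this tree (dup nodes only)
        by_node = {d.node.id: d for d in dups[base:]}
        for d in dups[base:]:
            n = d.node.parent
            while n is not None:
                a = by_node.get(n.id)
                if a is not None:
                    a.desc.append(d.idx)
                n = n.parent
    return dups


def rme_score(trees: Sequence[RootedGeneTree], species: SpeciesTree,
              species_of: Optional[Callable[[str], str]] = None,
              base_lambdas: Optional[Dict[int, int]] = None) -> MEScoreRooted:
    """Optimal minimum-episodes score for a set of rooted gene trees.

    With ``base_lambdas`` the solver treats the given per-node episode counts
    as free capacity (levels that already exist) and scores only the levels
    it has to add -- the incremental mode used when growing a background of
    committed trees one tree at a time.
    """
    base = dict(base_lambdas or {})
    dups = _collect_dups(trees, species, species_of)

    used: Dict[int, int] = {}            # species id -> max level used
    at_node: Dict[int, List[_Dup]] = {}  # species id -> dups placed there

    def assign(d: _Dup, s: TreeNode, level: int) -> None:
        d.slot = (s.id, level)
        at_node.setdefault(s.id, []).append(d)
        if level > used.get(s.id, 0):
            used[s.id] = level

    def next_level(d: _Dup, s_id: int) -> int:
        """1 + highest level of d's same-tree descendants already at s."""
        lvl = 0
        for d2 in at_node.get(s_id, ()):  # descendants were placed earlier
            if d2.idx in d.desc and d2.slot[1] > lvl:
                lvl = d2.slot[1]
        return lvl + 1

    tops: Dict[int, List[_Dup]] = {}
    for d in dups:
        tops.setdefault(d.top.id, []).append(d)

    for s in species.postorder():
        forced = sorted(tops.get(s.id, ()), key=lambda d: (d.tree, d.node.id))
        for d in forced:  # descendants first within a tree (post-order ids)
            if d.slot is None:  # may have been pulled below earlier
                assign(d, s, next_level(d, s.id))
        cap = max(used.get(s.id, 0), base.get(s.id, 0))
        if cap == 0:
            continue
        candidates = [d for d in dups
                      if d.slot is None and d.top is not s
                      and species.leq(d.bottom, s) and species.leq(s, d.top)]
        candidates.sort(key=lambda d: (-species.depth[d.bottom.id],
                                       d.tree, d.node.id))
        for d in candidates:
            if any(dups[i].slot is None for i in d.desc):
                continue  # an unassigned descendant would be trapped below
            lvl = next_level(d, s.id)
            if lvl <= cap:
                assign(d, s, lvl)

    score = sum(max(0, lvl - base.get(s_id, 0)) for s_id, lvl in used.items())
    lambdas = dict(base)
    for s_id, lvl in used.items():
        lambdas[s_id] = max(lambdas.get(s_id, 0), lvl)

    episodes: List[Episode] = []
    node_of = {n.id: n for n in species.postorder()}
    groups: Dict[Tuple[int, int], List[Tuple[int, TreeNode]]] = {}
    for d in dups:
        groups.setdefault(d.slot, []).append((d.tree, d.node))
    for (s_id, level) in sorted(groups):
        episodes.append(Episode(species_node=node_of[s_id], level=level,
                                members=sorted(groups[(s_id, level)],
                                               key=lambda m: (m[0], m[1].id))))
    assignment = {(d.tree, d.node.id): d.slot for d in dups}
    return MEScoreRooted(score=score, species=species, lambdas=lambdas,
                         episodes=episodes, assignment=assignment)


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

def _chain_length(placed: List[_Dup], all_dups: List[_Dup]) -> int:
    """Longest chain of comparable duplications among ``placed`` (one tree)."""
    placed = sorted(placed, key=lambda d: d.node.id)  # descendants first
    best: Dict[int, int] = {}
    out = 0
    for d in placed:
        b = 1
        for d2 in placed:
            if d2.idx in d.desc:
                b = max(b, best[d2.idx] + 1)
        best[d.idx] = b
        out = max(out, b)
    return out


def brute_force_rme(trees: Sequence[RootedGeneTree], species: SpeciesTree,
                    species_of: Optional[Callable[[str], str]] = None,
                    limit: int = 8) -> MEScoreRooted:
    """Exhaustive minimum over all interval-feasible monotone assignments.

    Test oracle for :func:`rme_score`; refuses instances with more than
    ``limit`` duplications.
    """
    dups = _collect_dups(trees, species, species_of)
    if len(dups) > limit:
        raise ValueError(f"brute force limited to {limit} duplications "
                         f"({len(dups)} present)")
    options = [species.path_up(d.bottom, d.top) for d in dups]
    node_of = {n.id: n for n in species.postorder()}

    best_score = None
    best_places: Optional[Tuple[TreeNode, ...]] = None
    for places in itertools.product(*options):
        ok = True
        for d in dups:
            for i in d.desc:  # descendant must sit at or below d's node
                if not species.leq(places[i], places[d.idx]):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        per_node: Dict[int, Dict[int, List[_Dup]]] = {}
        for d, p in zip(dups, places):
            per_node.setdefault(p.id, {}).setdefault(d.tree, []).append(d)
        score = sum(max(_chain_length(group, dups)
                        for group in by_tree.values())
                    for by_tree in per_node.values())
        if best_score is None or score < best_score:
            best_score = score
            best_places = places
    assert best_places is not None

    # reconstruct lambdas/episodes of one optimal assignment
    lambdas: Dict[int, int] = {}
    groups: Dict[Tuple[int, int], List[Tuple[int, TreeNode]]] = {}
    per_node: Dict[int, Dict[int, List[_Dup]]] = {}
    for d, p in zip(dups, best_places):
        per_node.setdefault(p.id, {}).setdefault(d.tree, []).append(d)
    assignment: Dict[Tuple[int, int], Tuple[int, int]] = {}
    for s_id, by_tree in per_node.items():
        lam = 0
        for t, group in by_tree.items():
            group = sorted(group, key=lambda d: d.node.id)
            level: Dict[int, int] = {}
            for d in group:
                lvl = 1 + max((level[i] for i in d.desc if i in level),
                              default=0)
                level[d.idx] = lvl
                lam = max(lam, lvl)
                groups.setdefault((s_id, lvl), []).append((t, d.node))
                assignment[(t, d.node.id)] = (s_id, lvl)
        lambdas[s_id] = lam
    episodes = [Episode(species_node=node_of[s_id], level=lvl,
                        members=sorted(m, key=lambda x: (x[0], x[1].id)))
                for (s_id, lvl), m in sorted(groups.items())]
    return MEScoreRooted(score=best_score, species=species, lambdas=lambdas,
                         episodes=episodes, assignment=assignment)
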