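"""Reconciliation under the duplication cost.

Rooted side: the least-common-ancestor (lca) mapping M sends every gene-tree
node to a species-tree node; an internal gene node g is a *duplication* iff
M(g) equals the image of one of its children, otherwise a *speciation*
(leaves included).  The duplication cost D(T, S) counts duplications.

Unrooted side: for an unrooted gene tree U every directed edge (u -> v)
carries the lca image of the subtree on the v side.  Rooting U on an edge e
induces a duplication cost D(U_e, S); the set of cost-minimising edges -- the
*plateau* U* -- is a connected subtree of U.  Edges are typed empty / single /
double by whether neither / one / both directed images hit the effective top
of the family (the lca of all species present in U), and nodes of the plateau
get roles that hold in *every* optimal rooting: plateau leaves are
super-speciations, internal plateau nodes away from the empty edge are
super-duplications, and internal nodes on the empty edge are conditional.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

from .trees import (Edge, RootedGeneTree, SpeciesTree, TreeError, TreeNode,
                    UnrootedGeneTree, _norm_edge)

__all__ = [
    "DUPLICATION", "SPECIATION",
    "LcaMapping", "lca_map", "dup_cost",
    "EdgeMaps", "edge_maps",
    "EMPTY", "SINGLE", "DOUBLE",
    "S2Star", "PlateauInfo", "classify_edges", "plateau",
]

DUPLICATION = "duplication"
SPECIATION = "speciation"

EMPTY = "empty"
SINGLE = "single"
DOUBLE = "double"

SUPER_DUPLICATION = "super-duplication"
SUPER_SPECIATION = "super-speciation"
CONDITIONAL = "conditional"


class LcaMapping:
    """lca mapping of a rooted gene tree into a species tree, with events."""

    def __init__(self, tree: RootedGeneTree, species: SpeciesTree,
                 species_of: Optional[Callable[[str], str]] = None):
        self.tree = tree
        self.species = species
        self._map: Dict[int, TreeNode] = {}
        self._isdup: Dict[int, bool] = {}
        for n in tree.postorder():
            if n.is_leaf:
                name = species_of(n.label) if species_of else n.label
                leaf = species.leaf_by_label.get(name)
                if leaf is None:
                    raise TreeError(
                        f"species {name!r} (gene leaf {n.label!r}) absent "
                        "from the species tree")
                self._map[n.id] = leaf
                self._isdup[n.id] = False
            else:
                a, b = n.children
                img = species.lca(self._map[a.id], self._map[b.id])
                self._map[n.id] = img
                self._isdup[n.id] = (img is self._map[a.id]
                                     or img is self._map[b.id])

    def image(self, node: TreeNode) -> TreeNode:
        return self._map[node.id]

    def is_duplication(self, node: TreeNode) -> bool:
        return self._isdup[node.id]

    def event(self, node: TreeNode) -> str:
        return DUPLICATION if self._isdup[node.id] else SPECIATION

    @property
    def duplications(self) -> List[TreeNode]:
        return [n for n in self.tree.postorder() if self._isdup[n.id]]

    @property
    def dup_count(self) -> int:
        return sum(1 for f in self._isdup.values() if f)


def lca_map(tree: RootedGeneTree, species: SpeciesTree,
            species_of: Optional[Callable[[str], str]] = None) -> LcaMapping:
    """Compute the lca mapping and per-node event flags (one post-order pass)."""
    return LcaMapping(tree, species, species_of)


def dup_cost(tree: RootedGeneTree, species: SpeciesTree,
             species_of: Optional[Callable[[str], str]] = None) -> int:
    """Duplication cost D(T, S): the number of duplication nodes."""
    return lca_map(tree, species, species_of).dup_count


# ---------------------------------------------------------------------------
# directed-edge maps on unrooted trees
# ---------------------------------------------------------------------------

class EdgeMaps:
    """Per-directed-edge lca images and duplication counts for an unrooted tree.

    ``image(u, v)`` is the lca image of the subtree on the v side when the
    edge {u, v} is cut; ``dup_count(u, v)`` the number of duplication nodes
    strictly inside that subtree (for any rooting in which v's parent lies on
    the u side).  Both directions of every edge are computed in O(|U|) by
    memoised message passing.
    """

    def __init__(self, U: UnrootedGeneTree, species: SpeciesTree,
                 species_of: Optional[Callable[[str], str]] = None):
        self.U = U
        self.species = species
        self._img: Dict[Tuple[int, int], TreeNode] = {}
        self._dup: Dict[Tuple[int, int], bool] = {}
        self._cnt: Dict[Tuple[int, int], int] = {}
        resolve = species_of or (lambda s: s)

        leaf_img: Dict[int, TreeNode] = {}
        for v in U.leaves:
            name = resolve(U.labels[v])
            leaf = species.leaf_by_label.get(name)
            if leaf is None:
                raise TreeError(
                    f"species {name!r} (gene leaf {U.labels[v]!r}) absent "
                    "from the species tree")
            leaf_img[v] = leaf

        # images, iteratively (avoids recursion limits on long paths)
        for start in U.directed_edges():
            if start in self._img:
                continue
            stack = [start]
            while stack:
                u, v = stack[-1]
                if (u, v) in self._img:
                    stack.pop()
                    continue
                if U.is_leaf(v):
                    self._img[(u, v)] = leaf_img[v]
                    stack.pop()
                    continue
                deps = [(v, w) for w in U.neighbors(v) if w != u]
                missing = [d for d in deps if d not in self._img]
                if missing:
                    stack.extend(missing)
                    continue
                self._img[(u, v)] = species.lca(self._img[deps[0]],
                                                self._img[deps[1]])
                stack.pop()

        # node duplication flags per direction, then subtree counts
        for (u, v), img in self._img.items():
            if U.is_leaf(v):
                self._dup[(u, v)] = False
            else:
                x, y = (w for w in U.neighbors(v) if w != u)
                self._dup[(u, v)] = (img is self._img[(v, x)]
                                     or img is self._img[(v, y)])
        for start in U.directed_edges():
            if start in self._cnt:
                continue
            stack = [start]
            while stack:
                u, v = stack[-1]
                if (u, v) in self._cnt:
                    stack.pop()
                    continue
                if U.is_leaf(v):
                    self._cnt[(u, v)] = 0
                    stack.pop()
                    continue
                deps = [(v, w) for w in U.neighbors(v) if w != u]
                missing = [d for d in deps if d not in self._cnt]
                if missing:
                    stack.extend(missing)
                    continue
                self._cnt[(u, v)] = (int(self._dup[(u, v)])
                                     + self._cnt[deps[0]] + self._cnt[deps[1]])
                stack.pop()

        u, v = U.directed_edges()[0]
        self.top: TreeNode = species.lca(self._img[(u, v)], self._img[(v, u)])

    def image(self, u: int, v: int) -> TreeNode:
        return self._img[(u, v)]

    def dup_count(self, u: int, v: int) -> int:
        return self._cnt[(u, v)]

    def is_dup_towards(self, u: int, v: int) -> bool:
        """Is node v a duplication when its parent lies on the u side?"""
        return self._dup[(u, v)]


def edge_maps(U: UnrootedGeneTree, species: SpeciesTree,
              species_of: Optional[Callable[[str], str]] = None) -> EdgeMaps:
    return EdgeMaps(U, species, species_of)


# ---------------------------------------------------------------------------
# edge types, plateau, S2 stars, node roles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class S2Star:
    """Star of three edges around ``center`` with exactly one empty edge."""
    center: int
    empty_edge: Edge
    single_edges: Tuple[Edge, Edge]


@dataclass
class PlateauInfo:
    """Edge types, optimal-rooting edge set U*, S2 stars and node roles."""
    U: UnrootedGeneTree
    species: SpeciesTree
    maps: EdgeMaps
    edge_types: Dict[Edge, str]
    costs: Dict[Edge, int]
    min_cost: int
    edges: frozenset  # the plateau U*
    empty_edge: Optional[Edge]
    double_edges: Tuple[Edge, ...]
    s2_stars: Tuple[S2Star, ...]
    roles: Dict[int, str] = field(default_factory=dict)

    @property
    def nodes(self) -> List[int]:
        out = set()
        for u, v in self.edges:
            out.update((u, v))
        return sorted(out)

    def plateau_degree(self, v: int) -> int:
        return sum(1 for u, w in self.edges if v in (u, w))

    @property
    def leaf_nodes(self) -> List[int]:
        return [v for v in self.nodes if self.plateau_degree(v) == 1]

    @property
    def internal_nodes(self) -> List[int]:
        return [v for v in self.nodes if self.plateau_degree(v) >= 2]

    def sorted_edges(self) -> List[Edge]:
        return sorted(self.edges)


def classify_edges(U: UnrootedGeneTree, species: SpeciesTree,
                   maps: Optional[EdgeMaps] = None,
                   species_of: Optional[Callable[[str], str]] = None
                   ) -> Dict[Edge, str]:
    """Type every edge empty / single / double against the family top.

    The comparison uses the effective top (lca of all species present in U)
    rather than the species-tree root, so families that do not span all
    species are handled identically to full-span ones.
    """
    maps = maps or EdgeMaps(U, species, species_of)
    top = maps.top
    out: Dict[Edge, str] = {}
    for u, v in U.edges():
        a = maps.image(v, u)  # image of the u side
        b = maps.image(u, v)  # image of the v side
        if a is top and b is top:
            out[(u, v)] = DOUBLE
        elif a is not top and b is not top:
            out[(u, v)] = EMPTY
        else:
            out[(u, v)] = SINGLE
    return out


def plateau(U: UnrootedGeneTree, species: SpeciesTree,
            species_of: Optional[Callable[[str], str]] = None) -> PlateauInfo:
    """Compute the plateau U* (argmin-cost rooting edges) with types and roles.

    The cost of rooting on e = {u, v} is the number of duplications in the two
    directed subtrees plus one for the new root unless e is empty (an empty
    edge roots at a speciation).
    """
    maps = EdgeMaps(U, species, species_of)
    types = classify_edges(U, species, maps)
    costs: Dict[Edge, int] = {}
    for u, v in U.edges():
        root_dup = 0 if types[(u, v)] == EMPTY else 1
        costs[(u, v)] = maps.dup_count(u, v) + maps.dup_count(v, u) + root_dup
    mincost = min(costs.values())
    edges = frozenset(e for e, c in costs.items() if c == mincost)

    empties = [e for e in edges if types[e] == EMPTY]
    if len(empties) > 1:
        raise TreeError("plateau with more than one empty edge (invalid input?)")
    empty_edge = empties[0] if empties else None
    doubles = tuple(sorted(e for e in edges if types[e] == DOUBLE))

    stars: List[S2Star] = []
    if empty_edge is not None:
        for center in empty_edge:
            if U.is_leaf(center):
                continue
            star_edges = [_norm_edge(center, w) for w in U.neighbors(center)]
            singles = tuple(sorted(e for e in star_edges if e != empty_edge))
            stars.append(S2Star(center=center, empty_edge=empty_edge,
                                single_edges=singles))

    info = PlateauInfo(U=U, species=species, maps=maps, edge_types=types,
                       costs=costs, min_cost=mincost, edges=edges,
                       empty_edge=empty_edge, double_edges=doubles,
                       s2_stars=tuple(stars))
    roles: Dict[int, str] = {}
    empty_nodes = set(empty_edge) if empty_edge else set()
    for v in info.nodes:
        if info.plateau_degree(v) == 1:
            roles[v] = SUPER_SPECIATION
        elif v in empty_nodes:
            roles[v] = CONDITIONAL
        else:
            roles[v] = SUPER_DUPLICATION
    info.roles = roles
    return info
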