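"""Equivalence classes on plateau edges and the unrooted decomposition.

Two plateau edges are ~-equivalent when their rootings share the same
*speciation frontier*: the set of maximal non-root speciation nodes.  There
are always 1, 3 or 5 classes.  A class containing the empty edge is *plain*
(a singleton -- its rooting is fixed); every other class is *complex*.

For a complex class X the decomposition detaches the maximal rooted subtrees
hanging off the class skeleton (their roots are speciations in every rooting
on X) and replaces each of them in the skeleton by a fresh copy of the
species tree below its mapping.  The resulting reduced unrooted tree U^X,
together with the detached trees Delta(U, X), scores exactly like the
original tree for any rooting on X -- this is what lets the exact solver
enumerate classes instead of individual rootings.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, FrozenSet, List, Optional, Tuple

from .reconcile import (SPECIATION, EdgeMaps, LcaMapping, PlateauInfo,
                        lca_map, plateau)
from .trees import (Edge, RootedGeneTree, SpeciesTree, TreeError, TreeNode,
                    UnrootedGeneTree, _norm_edge)

__all__ = [
    "frontier", "EquivClass", "EquivClassSet", "equiv_classes",
    "DecompositionResult", "decompose_class",
]

PLAIN = "plain"
COMPLEX = "complex"


def frontier(tree: RootedGeneTree, species: SpeciesTree,
             mapping: Optional[LcaMapping] = None,
             species_of: Optional[Callable[[str], str]] = None
             ) -> FrozenSet:
    """Speciation frontier: the maximal non-root speciation nodes.

    Nodes are identified by their ``source`` tag (the unrooted node id for
    rootings of an unrooted tree), so frontiers of different rootings of one
    tree are directly comparable.
    """
    mapping = mapping or lca_map(tree, species, species_of)
    out = []
    stack = list(tree.root.children)
    while stack:
        n = stack.pop()
        if not mapping.is_duplication(n):
            out.append(n.source if n.source is not None else n.id)
        else:
            stack.extend(n.children)
    return frozenset(out)


@dataclass(frozen=True)
class EquivClass:
    """One ~-equivalence class of plateau edges."""
    key: str          # "whole-plateau" or the defining S2-star edge
    edges: FrozenSet
    kind: str         # plain | complex

    @property
    def is_plain(self) -> bool:
        return self.kind == PLAIN

    def sorted_edges(self) -> List[Edge]:
        return sorted(self.edges)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class EquivClassSet:
    """All ~-classes of one unrooted tree, in deterministic order."""
    U: UnrootedGeneTree
    plateau: PlateauInfo
    classes: List[EquivClass]

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def is_multi(self) -> bool:
        """Does this tree contribute to the exponential budget (S2 star and
        more than one class)?"""
        return len(self.classes) > 1


def _plateau_component(info: PlateauInfo, start: int, blocked: int) -> FrozenSet:
    """Plateau edges reachable from ``start`` without passing ``blocked``."""
    adj: Dict[int, List[int]] = {}
    for u, v in info.edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    edges = set()
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for w in adj.get(v, ()):
            if w == blocked:
                continue
            edges.add(_norm_edge(v, w))
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return frozenset(edges)


def equiv_classes(U: UnrootedGeneTree, species: SpeciesTree,
                  info: Optional[PlateauInfo] = None,
                  species_of: Optional[Callable[[str], str]] = None
                  ) -> EquivClassSet:
    """Partition the plateau into ~-classes, built structurally.

    Without an empty edge the whole plateau is one (complex) class.  With an
    empty edge, the empty edge is its own plain class and every plateau
    single edge of an S2 star defines one complex class: that edge plus all
    plateau edges on its far side.
    """
    info = info or plateau(U, species, species_of)
    if info.empty_edge is None:
        classes = [EquivClass(key="whole-plateau", edges=info.edges,
                              kind=COMPLEX)]
        return EquivClassSet(U=U, plateau=info, classes=classes)

    classes = [EquivClass(key="empty", edges=frozenset([info.empty_edge]),
                          kind=PLAIN)]
    for star in sorted(info.s2_stars, key=lambda s: s.center):
        for e in star.single_edges:
            if e not in info.edges:
                continue
            a = e[0] if e[1] == star.center else e[1]
            comp = _plateau_component(info, a, star.center)
            classes.append(EquivClass(key=f"star:{e[0]}-{e[1]}",
                                      edges=frozenset({e}) | comp,
                                      kind=COMPLEX))
    covered = frozenset().union(*(c.edges for c in classes))
    if covered != info.edges or sum(len(c) for c in classes) != len(info.edges):
        raise TreeError("equivalence classes do not partition the plateau")
    return EquivClassSet(U=U, plateau=info, classes=classes)


# ---------------------------------------------------------------------------
# decomposition of one class
# ---------------------------------------------------------------------------

@dataclass
class DecompositionResult:
    """Detached trees Delta(U, X) and, for a complex class, the reduced tree.

    ``image_edges`` maps each original class edge to its counterpart in the
    reduced tree; padding nodes carry ``("pad", i, species_node_id)`` sources
    so episode reports can distinguish real gene nodes from species-tree
    copies.
    """
    cls: EquivClass
    delta: List[RootedGeneTree]
    reduced: Optional[UnrootedGeneTree]
    image_edges: Dict[Edge, Edge]
    rooting: Optional[RootedGeneTree]  # plain classes only


def decompose_class(U: UnrootedGeneTree, species: SpeciesTree,
                    cls: EquivClass,
                    info: Optional[PlateauInfo] = None,
                    species_of: Optional[Callable[[str], str]] = None
                    ) -> DecompositionResult:
    """Decompose one ~-class per the unrooted decomposition.

    Plain class: Delta = { the rooting on the empty edge }, no reduced tree.
    Complex class X: Delta = maximal subtrees hanging off the leaves of the
    class skeleton U|_X; the reduced tree replaces each of them by the
    species subtree below its lca image.
    """
    info = info or plateau(U, species, species_of)
    if cls.is_plain:
        (e,) = cls.edges
        return DecompositionResult(cls=cls, delta=[U.root_at(e)],
                                   reduced=None, image_edges={}, rooting=U.root_at(e))

    maps = info.maps
    deg: Dict[int, int] = {}
    xneigh: Dict[int, List[int]] = {}
    for u, v in cls.edges:
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
        xneigh.setdefault(u, []).append(v)
        xneigh.setdefault(v, []).append(u)
    x_leaves = sorted(v for v, d in deg.items() if d == 1)
    x_internal = sorted(v for v, d in deg.items() if d > 1)

    delta: List[RootedGeneTree] = []
    pad_for: Dict[int, RootedGeneTree] = {}
    for i, v in enumerate(x_leaves):
        (u,) = xneigh[v]
        tv = RootedGeneTree(U.subtree(v, away_from=u))
        delta.append(tv)
        image = maps.image(u, v)  # lca image of T_v
        pad = species.species_subtree(image)
        for n in pad.postorder():
            n.source = ("pad", i, n.source[1])
        pad_for[v] = pad

    # assemble the reduced unrooted tree
    next_id = 0
    new_id: Dict[int, int] = {}
    adjacency: Dict[int, List[int]] = {}
    labels: Dict[int, Optional[str]] = {}
    sources: Dict[int, object] = {}

    def fresh(label=None, source=None) -> int:
        nonlocal next_id
        i = next_id
        next_id += 1
        adjacency[i] = []
        labels[i] = label
        sources[i] = source
        return i

    for v in x_internal:
        new_id[v] = fresh(label=None, source=U.sources[v])
    for v in x_leaves:
        pad = pad_for[v]
        ids: Dict[int, int] = {}
        for n in pad.postorder():
            ids[n.id] = fresh(label=n.label, source=n.source)
        for n in pad.postorder():
            for c in n.children:
                adjacency[ids[n.id]].append(ids[c.id])
                adjacency[ids[c.id]].append(ids[n.id])
        new_id[v] = ids[pad.root.id]

    image_edges: Dict[Edge, Edge] = {}
    for u, v in sorted(cls.edges):
        a, b = new_id[u], new_id[v]
        adjacency[a].append(b)
        adjacency[b].append(a)
        image_edges[(u, v)] = _norm_edge(a, b)

    reduced = UnrootedGeneTree(adjacency, labels, sources,
                               allow_degenerate=True)
    return DecompositionResult(cls=cls, delta=delta, reduced=reduced,
                               image_edges=image_edges, rooting=None)
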