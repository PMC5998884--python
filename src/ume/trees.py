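"""Tree containers and newick I/O.

Three kinds of trees are used throughout the package:

* :class:`SpeciesTree` -- a rooted binary tree with uniquely labeled leaves.
  It is the fixed frame for reconciliation and supplies clusters, lca queries
  and the ancestor order ``a <= b`` ("a is below b on a root path").
* :class:`RootedGeneTree` -- a rooted binary tree whose leaves are labeled by
  species names (repeats allowed).
* :class:`UnrootedGeneTree` -- an undirected tree in which every internal
  node has degree exactly 3.  Nodes carry stable integer identifiers so that
  reconciliation state computed once on the unrooted tree can be reported on
  any of its rootings.

Newick reading goes through dendropy; writing is a plain recursive join
(no branch lengths are emitted, and input branch lengths are ignored).
"""
from __future__ import annotations

from typing import Callable, Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import dendropy

__all__ = [
    "TreeError",
    "TreeNode",
    "RootedGeneTree",
    "SpeciesTree",
    "UnrootedGeneTree",
    "parse_newick",
    "parse_newick_list",
    "make_species_map",
    "canonical_rooted",
    "canonical_unrooted",
]


class TreeError(ValueError):
    """Raised for malformed trees or newick input."""


# ---------------------------------------------------------------------------
# rooted trees
# ---------------------------------------------------------------------------

class TreeNode:
    """Node of a rooted tree.

    ``source`` records provenance: for rootings of an unrooted tree it holds
    the unrooted node identifier, for species-tree copies a ``("species", id)``
    tag, so that episode reports can refer back to original nodes.
    """

    __slots__ = ("id", "label", "parent", "children", "source")

    def __init__(self, label: Optional[str] = None,
                 children: Iterable["TreeNode"] = (),
                 source=None):
        self.id: Optional[int] = None
        self.label = label
        self.parent: Optional[TreeNode] = None
        self.children: List[TreeNode] = []
        self.source = source
        for c in children:
            self.add_child(c)

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        out, stack = [], [self]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def copy(self) -> "TreeNode":
        node = TreeNode(label=self.label, source=self.source)
        for c in self.children:
            node.add_child(c.copy())
        return node

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<TreeNode id={self.id} label={self.label!r}>"


def _write_newick(node: TreeNode) -> str:
    if node.is_leaf:
        return node.label or ""
    return "(" + ",".join(_write_newick(c) for c in node.children) + ")"


class _RootedTree:
    """Shared indexing behaviour for rooted trees.

    Node identifiers are assigned in post-order, so within one tree a
    descendant always has a smaller id than its ancestors.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.nodes: List[TreeNode] = list(root.postorder())
        for i, n in enumerate(self.nodes):
            n.id = i

    def postorder(self) -> Iterator[TreeNode]:
        return iter(self.nodes)

    @property
    def leaves(self) -> List[TreeNode]:
        return [n for n in self.nodes if n.is_leaf]

    def newick(self) -> str:
        return _write_newick(self.root) + ";"

    def __len__(self) -> int:
        return len(self.nodes)


class RootedGeneTree(_RootedTree):
    """Rooted binary gene tree; leaves labeled by species names (repeats ok).

    Single-leaf trees are permitted (they arise as detached subtrees in the
    unrooted decomposition); :func:`parse_newick` itself rejects trivial
    newick input.
    """

    def __init__(self, root: TreeNode):
        super().__init__(root)
        for n in self.nodes:
            if n.children and len(n.children) != 2:
                raise TreeError(
                    f"rooted gene tree must be binary (node with "
                    f"{len(n.children)} children)")
            if n.is_leaf and not n.label:
                raise TreeError("unlabeled leaf in gene tree")


class SpeciesTree(_RootedTree):
    """Rooted binary species tree with uniquely labeled leaves."""

    def __init__(self, root: TreeNode):
        super().__init__(root)
        labels = []
        for n in self.nodes:
            if n.children:
                if len(n.children) != 2:
                    raise TreeError("species tree must be binary")
            else:
                if not n.label:
                    raise TreeError("unlabeled species-tree leaf")
                labels.append(n.label)
        if len(labels) < 2:
            raise TreeError("species tree must have at least two leaves")
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate species-tree leaf labels")

        self.leaf_by_label: Dict[str, TreeNode] = {
            n.label: n for n in self.nodes if n.is_leaf}
        self._cluster: Dict[int, frozenset] = {}
        for n in self.nodes:  # post-order: children first
            if n.is_leaf:
                self._cluster[n.id] = frozenset([n.label])
            else:
                self._cluster[n.id] = frozenset().union(
                    *(self._cluster[c.id] for c in n.children))
        self.node_by_cluster: Dict[frozenset, TreeNode] = {
            self._cluster[n.id]: n for n in self.nodes}
        self.depth: Dict[int, int] = {}
        self._anc: Dict[int, frozenset] = {}
        for n in self.root.preorder():
            if n.parent is None:
                self.depth[n.id] = 0
                self._anc[n.id] = frozenset([n.id])
            else:
                self.depth[n.id] = self.depth[n.parent.id] + 1
                self._anc[n.id] = self._anc[n.parent.id] | {n.id}

    # -- order and lca ------------------------------------------------------

    def cluster(self, v: TreeNode) -> frozenset:
        return self._cluster[v.id]

    def leq(self, a: TreeNode, b: TreeNode) -> bool:
        """True iff ``a`` is ``b`` or a descendant of ``b`` (a below b)."""
        return b.id in self._anc[a.id]

    def lca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        while a is not b:
            if self.depth[a.id] >= self.depth[b.id]:
                a = a.parent
            else:
                b = b.parent
        return a

    def lca_of(self, nodes: Sequence[TreeNode]) -> TreeNode:
        it = iter(nodes)
        acc = next(it)
        for n in it:
            acc = self.lca(acc, n)
        return acc

    def path_up(self, bottom: TreeNode, top: TreeNode) -> List[TreeNode]:
        """Species nodes from ``bottom`` to ``top`` inclusive (bottom <= top)."""
        if not self.leq(bottom, top):
            raise TreeError("path_up: bottom is not below top")
        out, n = [], bottom
        while n is not top:
            out.append(n)
            n = n.parent
        out.append(top)
        return out

    def species_subtree(self, v: TreeNode) -> RootedGeneTree:
        """A fresh rooted gene tree copying the species tree below ``v``.

        Used as padding in the unrooted decomposition: a detached subtree is
        replaced by the species-tree copy rooted at its mapping.
        """
        def build(n: TreeNode) -> TreeNode:
            return TreeNode(label=n.label,
                            children=[build(c) for c in n.children],
                            source=("species", n.id))
        return RootedGeneTree(build(v))

    def cluster_string(self, v: TreeNode) -> str:
        names = sorted(self.cluster(v))
        if all(len(s) == 1 for s in names):
            return "".join(names)
        return ",".join(names)


# ---------------------------------------------------------------------------
# unrooted gene trees
# ---------------------------------------------------------------------------

Edge = Tuple[int, int]


def _norm_edge(u: int, v: int) -> Edge:
    return (u, v) if u < v else (v, u)


class UnrootedGeneTree:
    """Undirected gene tree; every internal node has degree exactly 3.

    ``allow_degenerate`` relaxes the ">= 3 leaves" requirement for reduced
    trees built internally by the decomposition (which can shrink to a single
    edge between two padded subtrees); parsed input is always validated
    strictly.
    """

    def __init__(self, adjacency: Dict[int, Sequence[int]],
                 labels: Dict[int, Optional[str]],
                 sources: Optional[Dict[int, object]] = None,
                 allow_degenerate: bool = False):
        self._adj: Dict[int, List[int]] = {
            v: sorted(ws) for v, ws in adjacency.items()}
        self.labels: Dict[int, Optional[str]] = dict(labels)
        self.sources: Dict[int, object] = dict(sources or {})
        for v in self._adj:
            self.sources.setdefault(v, v)
        self._validate(allow_degenerate)

    def _validate(self, allow_degenerate: bool) -> None:
        n = len(self._adj)
        if n < 2:
            raise TreeError("unrooted tree needs at least two nodes")
        m = sum(len(ws) for ws in self._adj.values())
        if m != 2 * (n - 1):
            raise TreeError("unrooted tree must be acyclic and connected")
        seen = set()
        stack = [next(iter(self._adj))]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(self._adj[v])
        if len(seen) != n:
            raise TreeError("unrooted tree is disconnected")
        for v, ws in self._adj.items():
            if len(ws) == 1:
                if not self.labels.get(v):
                    raise TreeError("unlabeled leaf in unrooted tree")
            elif len(ws) != 3:
                raise TreeError(
                    f"internal node of degree {len(ws)} in unrooted tree "
                    "(every internal node must have degree 3)")
        if not allow_degenerate and len(self.leaves) < 3:
            raise TreeError("unrooted gene tree needs at least 3 leaves")

    # -- structure ----------------------------------------------------------

    @classmethod
    def from_rooted(cls, tree: RootedGeneTree,
                    allow_degenerate: bool = False) -> "UnrootedGeneTree":
        """Dissolve the root of a rooted binary tree into an undirected edge."""
        root = tree.root
        if len(root.children) != 2:
            raise TreeError("can only unroot a binary rooted tree")
        if len(tree.leaves) < 3 and not allow_degenerate:
            raise TreeError("cannot unroot a tree with fewer than 3 leaves")
        ids: Dict[TreeNode, int] = {}
        i = 0
        for n in tree.postorder():
            if n is root:
                continue
            ids[n] = i
            i += 1
        adjacency: Dict[int, List[int]] = {v: [] for v in range(i)}
        labels: Dict[int, Optional[str]] = {}
        sources: Dict[int, object] = {}
        for n, v in ids.items():
            labels[v] = n.label if n.is_leaf else None
            sources[v] = n.source if n.source is not None else v
            for c in n.children:
                adjacency[v].append(ids[c])
                adjacency[ids[c]].append(v)
        a, b = (ids[c] for c in root.children)
        adjacency[a].append(b)
        adjacency[b].append(a)
        return cls(adjacency, labels, sources, allow_degenerate=allow_degenerate)

    def neighbors(self, v: int) -> List[int]:
        return self._adj[v]

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def is_leaf(self, v: int) -> bool:
        return len(self._adj[v]) == 1

    @property
    def node_ids(self) -> List[int]:
        return sorted(self._adj)

    @property
    def leaves(self) -> List[int]:
        return [v for v in sorted(self._adj) if self.is_leaf(v)]

    @property
    def internal_nodes(self) -> List[int]:
        return [v for v in sorted(self._adj) if not self.is_leaf(v)]

    def edges(self) -> List[Edge]:
        out = set()
        for v, ws in self._adj.items():
            for w in ws:
                out.add(_norm_edge(v, w))
        return sorted(out)

    def directed_edges(self) -> List[Tuple[int, int]]:
        return sorted((v, w) for v, ws in self._adj.items() for w in ws)

    def has_edge(self, e: Edge) -> bool:
        u, v = e
        return v in self._adj.get(u, ())

    def __len__(self) -> int:
        return len(self._adj)

    # -- rooting ------------------------------------------------------------

    def subtree(self, v: int, away_from: int) -> TreeNode:
        """Rooted copy of the subtree at ``v`` on the far side of ``away_from``."""
        node = TreeNode(label=self.labels.get(v), source=self.sources[v])
        for w in self._adj[v]:
            if w != away_from:
                node.add_child(self.subtree(w, v))
        return node

    def root_at(self, e: Edge) -> RootedGeneTree:
        """Root on edge ``e``: a new root node subdivides the edge.

        Node provenance (``source``) is preserved so that plateau and class
        results computed on the unrooted tree can be read off the rooting.
        """
        u, v = e
        if not self.has_edge(e):
            raise TreeError(f"edge {e} not in unrooted tree")
        root = TreeNode(children=[self.subtree(u, v), self.subtree(v, u)])
        return RootedGeneTree(root)

    # -- output -------------------------------------------------------------

    def newick(self) -> str:
        internal = self.internal_nodes
        if not internal:  # degenerate two-leaf tree
            a, b = sorted(self._adj)
            return f"({self.labels[a]},{self.labels[b]});"
        center = internal[0]
        parts = [_write_newick(self.subtree(w, center))
                 for w in self._adj[center]]
        return "(" + ",".join(parts) + ");"

    def species_labels(self) -> List[str]:
        return [self.labels[v] for v in self.leaves]


# ---------------------------------------------------------------------------
# newick parsing
# ---------------------------------------------------------------------------

def _from_dendropy(dnode) -> TreeNode:
    if not dnode.child_nodes():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return TreeNode(label=label)
    return TreeNode(label=dnode.label,
                    children=[_from_dendropy(c) for c in dnode.child_nodes()])


def _check_binary(root: TreeNode, what: str) -> None:
    for n in root.preorder():
        if n.children and len(n.children) != 2:
            raise TreeError(
                f"{what}: multifurcating or unary node "
                f"({len(n.children)} children)")


def _unrooted_from_structure(root: TreeNode) -> UnrootedGeneTree:
    kids = root.children
    if len(kids) == 2:
        dissolve = True
    elif len(kids) == 3:
        dissolve = False
    else:
        raise TreeError(
            "unrooted newick must be a rooted binary string or have a "
            "top-level trifurcation")
    for n in root.preorder():
        if n is root:
            continue
        if n.children and len(n.children) != 2:
            raise TreeError("multifurcation inside unrooted gene tree")
    ids: Dict[TreeNode, int] = {}
    i = 0
    for n in root.postorder():
        if dissolve and n is root:
            continue
        ids[n] = i
        i += 1
    adjacency: Dict[int, List[int]] = {v: [] for v in range(i)}
    labels: Dict[int, Optional[str]] = {}
    for n, v in ids.items():
        labels[v] = n.label if n.is_leaf else None
        for c in n.children:
            adjacency[v].append(ids[c])
            adjacency[ids[c]].append(v)
    if dissolve:
        a, b = (ids[c] for c in root.children)
        adjacency[a].append(b)
        adjacency[b].append(a)
    return UnrootedGeneTree(adjacency, labels)


def parse_newick_list(text: str, mode: str = "rooted") -> list:
    """Parse a newick string holding one or more ``;``-terminated trees.

    ``mode`` is one of ``"species"``, ``"rooted"``, ``"unrooted"``.  Branch
    lengths, if present, are ignored.
    """
    if mode not in ("species", "rooted", "unrooted"):
        raise ValueError(f"unknown parse mode {mode!r}")
    if not text.strip():
        return []
    try:
        tl = dendropy.TreeList.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True, suppress_leaf_node_taxa=True)
    except Exception as exc:
        raise TreeError(f"newick parse error: {exc}") from exc
    out = []
    for dtree in tl:
        root = _from_dendropy(dtree.seed_node)
        if mode == "species":
            _check_binary(root, "species tree")
            out.append(SpeciesTree(root))
        elif mode == "rooted":
            _check_binary(root, "rooted gene tree")
            tree = RootedGeneTree(root)
            if len(tree.leaves) < 2:
                raise TreeError("rooted gene tree must have >= 2 leaves")
            out.append(tree)
        else:
            out.append(_unrooted_from_structure(root))
    return out


def parse_newick(text: str, mode: str = "rooted"):
    """Parse exactly one newick tree (see :func:`parse_newick_list`)."""
    trees = parse_newick_list(text, mode)
    if len(trees) != 1:
        raise TreeError(f"expected exactly one tree, found {len(trees)}")
    return trees[0]


# ---------------------------------------------------------------------------
# gene -> species label resolution
# ---------------------------------------------------------------------------

def make_species_map(mode: str = "exact", separator: str = "_",
                     table: Optional[Dict[str, str]] = None
                     ) -> Callable[[str], str]:
    """Build a gene-label -> species-name resolver.

    exact      leaf labels are species names (the default assumed throughout);
    separator  labels like ``GENE_SPECIES``: the species is the field after
               the last separator;
    table      explicit two-column mapping (gene label -> species).
    """
    if mode == "exact":
        return lambda label: label
    if mode == "separator":
        def by_sep(label: str) -> str:
            if separator not in label:
                raise TreeError(
                    f"gene label {label!r} lacks separator {separator!r}")
            return label.rsplit(separator, 1)[1]
        return by_sep
    if mode in ("file", "table"):
        if table is None:
            raise ValueError("table mode requires a mapping")
        def by_table(label: str) -> str:
            try:
                return table[label]
            except KeyError:
                raise TreeError(f"gene label {label!r} not in mapping") from None
        return by_table
    raise ValueError(f"unknown species-map mode {mode!r}")


# ---------------------------------------------------------------------------
# canonical forms (label-based, order-insensitive) for comparisons
# ---------------------------------------------------------------------------

def canonical_rooted(tree) -> str:
    """Canonical newick-like string of a rooted tree (children sorted)."""
    node = tree.root if hasattr(tree, "root") else tree

    def canon(n: TreeNode) -> str:
        if n.is_leaf:
            return n.label or ""
        return "(" + ",".join(sorted(canon(c) for c in n.children)) + ")"
    return canon(node)


def canonical_unrooted(U: UnrootedGeneTree) -> str:
    """Canonical string of an unrooted tree (minimum over display centers)."""
    internal = U.internal_nodes
    if not internal:
        return "(" + ",".join(sorted(U.labels[v] for v in U.leaves)) + ")"
    forms = []
    for center in internal:
        parts = sorted(_canon_treenode(U.subtree(w, center))
                       for w in U.neighbors(center))
        forms.append("(" + ",".join(parts) + ")")
    return min(forms)


def _canon_treenode(n: TreeNode) -> str:
    if n.is_leaf:
        return n.label or ""
    return "(" + ",".join(sorted(_canon_treenode(c) for c in n.children)) + ")"
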