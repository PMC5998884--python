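"""Explicit duplication-loss-speciation (DLS) evolutionary scenarios.

A DLS tree records a full gene-family history inside a species tree: gene
sequence leaves (``a``), lost lineages (``A-`` where A is the species set of
the lost lineage), duplication nodes (``(R1,R2)+`` -- both children carry the
same species set) and speciation nodes (``(R1,R2)~`` -- disjoint species
sets).  ``gt`` extracts the observable gene tree by pruning loss-only parts
and contracting degree-2 nodes.

A scenario is compatible with a species tree S when every node's species set
is a cluster of S.  The episode score of a set of compatible scenarios is

    MES(R, S) = sum over species nodes v of  max over scenarios T of
                duppath(T, v)

where duppath(T, v) is the longest chain of comparable duplication nodes of T
whose species set equals the cluster of v.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .trees import RootedGeneTree, SpeciesTree, TreeError, TreeNode

__all__ = [
    "DLSNode", "DLSTree", "DLSError",
    "parse_dls", "write_dls", "gt", "mes_of_scenarios", "duppath",
]

GENE = "gene"
LOSS = "loss"
DUP = "duplication"
SPEC = "speciation"

_TILDES = ("~", "∼")  # ASCII tilde and the typographic one


class DLSError(ValueError):
    """Malformed DLS string or invalid scenario."""


@dataclass
class DLSNode:
    kind: str                      # gene | loss | duplication | speciation
    species: frozenset             # species set of the subtree
    label: Optional[str] = None    # gene leaves: the species name
    children: List["DLSNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.kind in (GENE, LOSS)

    def postorder(self):
        out, stack = [], [self]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)


class DLSTree:
    """A validated DLS scenario tree."""

    def __init__(self, root: DLSNode, tilde: str = "~"):
        self.root = root
        self.tilde = tilde  # glyph used when writing (round-trip stability)
        self._validate()

    def _validate(self) -> None:
        for n in self.root.postorder():
            if n.is_leaf:
                if not n.species:
                    raise DLSError("loss leaf with empty species set")
                continue
            if len(n.children) != 2:
                raise DLSError("internal DLS node must have two children")
            a, b = n.children
            if n.kind == DUP:
                if a.species != b.species:
                    raise DLSError(
                        "duplication children carry unequal species sets: "
                        f"{sorted(a.species)} vs {sorted(b.species)}")
            elif n.kind == SPEC:
                if a.species & b.species:
                    raise DLSError(
                        "speciation children carry overlapping species sets")
            else:
                raise DLSError(f"unknown DLS node kind {n.kind!r}")

    def postorder(self):
        return self.root.postorder()

    @property
    def species(self) -> frozenset:
        return self.root.species

    @property
    def duplications(self) -> List[DLSNode]:
        return [n for n in self.root.postorder() if n.kind == DUP]

    @property
    def gene_leaves(self) -> List[DLSNode]:
        return [n for n in self.root.postorder() if n.kind == GENE]

    def write(self, species_delimiter: Optional[str] = None) -> str:
        return write_dls(self, species_delimiter)

    def is_compatible(self, species: SpeciesTree) -> bool:
        clusters = set(species.node_by_cluster)
        return all(n.species in clusters for n in self.root.postorder())


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

_SPECIAL = set("(),+-;") | set(_TILDES) | {" ", "\t", "\n", "\r"}


def parse_dls(text: str, species_delimiter: Optional[str] = None) -> DLSTree:
    """Parse a DLS bracket string.

    Grammar: gene leaf = species name; loss leaf = species-set token followed
    by ``-``; internal = ``(X,Y)`` followed by ``+`` (duplication) or ``~`` /
    the typographic tilde (speciation).  The loss token is the concatenation
    of single-character species names by default; pass ``species_delimiter``
    to split multi-character names instead.
    """
    s = text.strip()
    if s.endswith(";"):
        s = s[:-1]
    pos = 0
    seen_tilde = "~"

    def skip_ws():
        nonlocal pos
        while pos < len(s) and s[pos] in " \t\r\n":
            pos += 1

    def token() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in _SPECIAL:
            pos += 1
        if pos == start:
            raise DLSError(f"expected a name at position {start} in {s!r}")
        return s[start:pos]

    def loss_set(tok: str) -> frozenset:
        if species_delimiter:
            return frozenset(t for t in tok.split(species_delimiter) if t)
        return frozenset(tok)

    def node() -> DLSNode:
        nonlocal pos, seen_tilde
        skip_ws()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            left = node()
            skip_ws()
            if pos >= len(s) or s[pos] != ",":
                raise DLSError(f"expected ',' at position {pos} in {s!r}")
            pos += 1
            right = node()
            skip_ws()
            if pos >= len(s) or s[pos] != ")":
                raise DLSError(f"expected ')' at position {pos} in {s!r}")
            pos += 1
            skip_ws()
            if pos >= len(s) or (s[pos] != "+" and s[pos] not in _TILDES):
                raise DLSError(
                    f"expected '+' or '~' after ')' at position {pos}")
            if s[pos] == "+":
                kind = DUP
            else:
                kind = SPEC
                seen_tilde = s[pos]
            pos += 1
            return DLSNode(kind=kind, species=left.species | right.species,
                           children=[left, right])
        tok = token()
        skip_ws()
        if pos < len(s) and s[pos] == "-":
            pos += 1
            return DLSNode(kind=LOSS, species=loss_set(tok))
        return DLSNode(kind=GENE, species=frozenset([tok]), label=tok)

    root = node()
    skip_ws()
    if pos != len(s):
        raise DLSError(f"trailing characters at position {pos} in {s!r}")
    return DLSTree(root, tilde=seen_tilde)


def write_dls(tree: DLSTree, species_delimiter: Optional[str] = None) -> str:
    delim = species_delimiter or ""
    tilde = tree.tilde

    def w(n: DLSNode) -> str:
        if n.kind == GENE:
            return n.label
        if n.kind == LOSS:
            return delim.join(sorted(n.species)) + "-"
        mark = "+" if n.kind == DUP else tilde
        return "(" + w(n.children[0]) + "," + w(n.children[1]) + ")" + mark
    return w(tree.root)


# ---------------------------------------------------------------------------
# gene-tree extraction and scoring
# ---------------------------------------------------------------------------

def gt(tree: DLSTree) -> RootedGeneTree:
    """Extract the gene tree: prune loss-only parts, contract unary nodes."""
    def build(n: DLSNode) -> Optional[TreeNode]:
        if n.kind == GENE:
            return TreeNode(label=n.label)
        if n.kind == LOSS:
            return None
        kids = [k for k in (build(c) for c in n.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return TreeNode(children=kids)
    root = build(tree.root)
    if root is None:
        raise DLSError("scenario has no gene sequences")
    return RootedGeneTree(root)


def duppath(tree: DLSTree, cluster: frozenset) -> int:
    """Longest chain of comparable duplications with the given species set."""
    def down(n: DLSNode, depth: int) -> int:
        here = depth + 1 if (n.kind == DUP and n.species == cluster) else depth
        if n.is_leaf:
            return here
        return max(down(c, here) for c in n.children)
    return down(tree.root, 0)


def mes_of_scenarios(scenarios: Sequence[DLSTree],
                     species: SpeciesTree) -> int:
    """Episode score of explicit scenarios: sum over species nodes of the
    largest per-scenario duplication chain at that node's cluster."""
    for i, t in enumerate(scenarios):
        if not t.is_compatible(species):
            bad = next(sorted(n.species) for n in t.root.postorder()
                       if n.species not in species.node_by_cluster)
            raise DLSError(
                f"scenario {i} incompatible with the species tree "
                f"(cluster {bad} missing)")
    total = 0
    for v in species.postorder():
        c = species.cluster(v)
        total += max((duppath(t, c) for t in scenarios), default=0)
    return total
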