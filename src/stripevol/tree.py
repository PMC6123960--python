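"""Phylogenetic tree container and Brownian-motion covariance utilities.

The tree is the substrate of every likelihood in the package: a rooted,
binary (after polytomy resolution), branch-length-bearing phylogeny with
unique tip labels.  Newick/Nexus reading and writing is delegated to
:mod:`dendropy`; internally the tree is stored as flat arrays in postorder,
which is the layout the pruning-algorithm likelihoods want.

Branch lengths are in time units (Myr for the clownfish data).  A missing
branch length is an error, never silently defaulted: the downstream
likelihoods are time-calibrated and a unit-branch default would corrupt
them.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TreeParseError",
    "parse_tree",
    "is_ultrametric",
    "vcv_matrix",
    "reconcile",
    "ReconciliationReport",
]


class TreeParseError(ValueError):
    """Raised when serialized tree text cannot be parsed."""


def _check_newick_structure(text: str) -> None:
    """Pre-scan Newick text for structural errors, reporting the character
    position of the first problem (dendropy's own messages are less precise)."""
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise TreeParseError(
                    f"unbalanced ')' at character position {pos}"
                )
        elif ch == ";":
            if depth != 0:
                raise TreeParseError(
                    f"unbalanced '(' — {depth} unclosed at ';' (character position {pos})"
                )
    if depth != 0:
        raise TreeParseError(
            f"unbalanced '(' — {depth} unclosed at end of text (character position {len(text)})"
        )


@dataclass
class PhyloTree:
    """Rooted phylogeny stored as flat postorder arrays.

    Nodes are integer ids ``0 .. n_nodes-1``; tips occupy ``0 .. n_tips-1``
    in the order of ``tip_labels``.  ``parent[root] == -1`` and
    ``branch_lengths[root] == 0``.
    """

    tip_labels: list[str]
    parent: np.ndarray          # (n_nodes,) int
    children: list[list[int]]   # per-node child ids (empty for tips)
    branch_lengths: np.ndarray  # (n_nodes,) float, subtending branch
    postorder: np.ndarray = field(init=False)  # tips before parents
    root: int = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.parent)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dupes = sorted({t for t in self.tip_labels if self.tip_labels.count(t) > 1})
            raise TreeParseError(f"duplicate tip labels: {dupes}")
        bl = np.asarray(self.branch_lengths, dtype=float)
        nonroot = np.arange(n) != self.root
        if not np.all(np.isfinite(bl[nonroot])) or np.any(bl[nonroot] < 0):
            raise ValueError("all non-root branch lengths must be finite and >= 0")
        self.branch_lengths = bl
        # postorder: iterative DFS, children pushed so leftmost is visited first
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.postorder = np.array(order[::-1], dtype=int)

    # -- basic queries -----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node (preorder accumulation)."""
        depth = np.zeros(self.n_nodes)
        for v in self.postorder[::-1]:
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.branch_lengths[v]
        return depth

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[: self.n_tips]

    def depth(self) -> float:
        """Tree height: maximum root-to-tip distance."""
        return float(self.tip_depths().max())

    def total_length(self) -> float:
        mask = np.arange(self.n_nodes) != self.root
        return float(self.branch_lengths[mask].sum())

    def tip_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        dtree = dtree.clone(depth=1)
        n_poly = sum(1 for nd in dtree.preorder_node_iter() if len(nd.child_nodes()) > 2)
        if n_poly:
            warnings.warn(
                f"resolving {n_poly} polytomies with zero-length branches",
                stacklevel=3,
            )
            dtree.resolve_polytomies()
            for nd in dtree.preorder_node_iter():
                if nd.edge.length is None and nd.parent_node is not None:
                    nd.edge.length = 0.0
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        labels: list[str] = []
        tip_ids: list[int] = []
        for i, nd in enumerate(nodes):
            if not nd.child_nodes():
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeParseError(f"unlabeled tip at node {i}")
                labels.append(nd.taxon.label.replace(" ", "_"))
                tip_ids.append(i)
        # reorder so tips come first, in label order of appearance
        remap = {}
        for new, old in enumerate(tip_ids):
            remap[old] = new
        nxt = len(tip_ids)
        for i in range(len(nodes)):
            if i not in remap:
                remap[i] = nxt
                nxt += 1
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        blen = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        for i, nd in enumerate(nodes):
            j = remap[i]
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise TreeParseError(
                        "branch length missing on a non-root edge; time-calibrated "
                        "analyses require explicit branch lengths"
                    )
                parent[j] = remap[index[id(nd.parent_node)]]
                blen[j] = float(nd.edge.length)
            children[j] = []  # filled below
        for i, nd in enumerate(nodes):
            j = remap[i]
            for c in nd.child_nodes():
                children[j].append(remap[index[id(c)]])
        return cls(tip_labels=labels, parent=parent, children=children, branch_lengths=blen)

    def to_newick(self, precision: int = 12) -> str:
        """Serialize as Newick; branch lengths with ``precision`` significant digits."""
        fmt = f"%.{precision}g"

        def rec(v: int) -> str:
            if self.is_tip(v):
                core = self.tip_labels[v]
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return core
            return core + ":" + (fmt % self.branch_lengths[v])

        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return rec(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick")

    def prune_to(self, keep: list[str]) -> "PhyloTree":
        """Return the induced tree on ``keep`` (suppressing unifurcations)."""
        missing = sorted(set(keep) - set(self.tip_labels))
        if missing:
            raise ValueError(f"tips not in tree: {missing}")
        dtree = self.to_dendropy()
        taxa = [t for t in dtree.taxon_namespace if t.label.replace(" ", "_") in set(keep)]
        dtree.retain_taxa(taxa)
        return PhyloTree.from_dendropy(dtree)


def parse_tree(text: str, format: str = "newick") -> PhyloTree:
    """Parse serialized tree text (``newick`` or ``nexus``) into a PhyloTree.

    Round trip through :meth:`PhyloTree.to_newick` preserves topology, labels
    and branch lengths to at least 10 significant digits.
    """
    fmt = format.lower()
    if fmt not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format: {format!r}")
    if fmt == "newick":
        _check_newick_structure(text)
    try:
        dtree = dendropy.Tree.get(
            file=io.StringIO(text),
            schema=fmt,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"could not parse {fmt} tree: {exc}") from exc
    return PhyloTree.from_dendropy(dtree)


def is_ultrametric(tree: PhyloTree, rel_tol: float = 1e-6) -> bool:
    """True iff all root-to-tip distances agree within ``rel_tol`` of their mean."""
    if tree.n_tips < 2:
        raise ValueError("ultrametricity needs >= 2 tips")
    d = tree.tip_depths()
    mean = d.mean()
    if mean == 0:
        return bool(np.all(d == 0))
    return bool(np.all(np.abs(d - mean) <= rel_tol * mean))


def vcv_matrix(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion phylogenetic variance–covariance matrix.

    Entry (a, b) is the shared root-path length of tips a and b, i.e. the
    depth of their most recent common ancestor; the diagonal is the
    root-to-tip distance.  Returns (matrix, tip_labels).
    """
    n = tree.n_tips
    depth = tree.node_depths()
    C = np.zeros((n, n))
    # tips under each node, built in postorder; cross-child pairs share the node
    tipsets: dict[int, np.ndarray] = {}
    for v in tree.postorder:
        if tree.is_tip(v):
            tipsets[v] = np.array([v], dtype=int)
            C[v, v] = depth[v]
        else:
            kids = tree.children[v]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    a, b = tipsets[kids[i]], tipsets[kids[j]]
                    C[np.ix_(a, b)] = depth[v]
                    C[np.ix_(b, a)] = depth[v]
            tipsets[v] = np.concatenate([tipsets[c] for c in kids])
    return C, list(tree.tip_labels)


@dataclass
class ReconciliationReport:
    """Tip-label vs trait-table reconciliation (exact, case-sensitive match)."""

    tips_missing_traits: list[str]
    traits_missing_tips: list[str]
    matched: list[str]

    @property
    def fully_matched(self) -> bool:
        return not self.tips_missing_traits and not self.traits_missing_tips

    def __str__(self) -> str:
        return (
            f"matched: {len(self.matched)}; "
            f"tips without traits: {self.tips_missing_traits or 'none'}; "
            f"trait rows without tips: {self.traits_missing_tips or 'none'}"
        )


def reconcile(tree: PhyloTree, species: list[str]) -> ReconciliationReport:
    """Compare tree tip labels against a trait-table species list."""
    tips = set(tree.tip_labels)
    sp = set(species)
    return ReconciliationReport(
        tips_missing_traits=sorted(tips - sp),
        traits_missing_tips=sorted(sp - tips),
        matched=sorted(tips & sp),
    )
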