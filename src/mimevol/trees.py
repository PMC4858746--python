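"""Rooted, time-scaled phylogenetic trees.

The package-internal tree is a flat, array-indexed structure optimized for
repeated post-order sweeps (likelihood evaluation, trait simulation).
Newick parsing and serialization are delegated to :mod:`dendropy`; the
internal representation is converted from/to a :class:`dendropy.Tree`.

Node numbering convention: tips are ``0 .. n_tips-1`` (in the order tip
labels are first encountered), internal nodes follow, and the root is the
last node. Branch lengths are in Myr and attach to the branch *above* each
non-root node.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Tree", "parse_newick", "write_newick", "TreeError"]


class TreeError(ValueError):
    """Malformed tree or tree/data mismatch."""


@dataclass
class Tree:
    """Rooted tree with branch lengths in Myr.

    Attributes
    ----------
    parent : ndarray of int
        ``parent[i]`` is the parent node id of node ``i``; the root has -1.
    children : list of list of int
        Child ids per node (empty for tips). Polytomies are permitted.
    branch_length : ndarray of float
        Length of the branch above each node; 0.0 for the root.
    labels : list of str or None
        Tip labels for nodes ``0 .. n_tips-1``; internal labels optional.
    """

    parent: np.ndarray
    children: list
    branch_length: np.ndarray
    labels: list
    n_tips: int
    _postorder: np.ndarray = field(default=None, repr=False)
    _heights: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.parent)
        if np.sum(self.parent < 0) != 1:
            raise TreeError("tree must have exactly one root")
        if np.any(self.branch_length < 0):
            raise TreeError("negative branch length")
        tips = [lbl for lbl in self.labels[: self.n_tips]]
        if len(set(tips)) != self.n_tips:
            raise TreeError("tip labels must be unique")
        if n != len(self.children) or n != len(self.branch_length):
            raise TreeError("inconsistent node arrays")

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.where(self.parent < 0)[0][0])

    @property
    def tip_labels(self) -> list:
        return list(self.labels[: self.n_tips])

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    def postorder(self) -> np.ndarray:
        """Node ids in post-order (children before parents)."""
        if self._postorder is None:
            order, stack = [], [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(reversed(self.children[v]))  # keep child order in preorder
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    def node_heights(self) -> np.ndarray:
        """Distance from the root to each node (root = 0)."""
        if self._heights is None:
            h = np.zeros(self.n_nodes)
            for v in self.preorder():
                p = self.parent[v]
                if p >= 0:
                    h[v] = h[p] + self.branch_length[v]
            self._heights = h
        return self._heights

    def depth(self) -> float:
        return float(self.node_heights().max())

    def total_branch_length(self) -> float:
        bl = self.branch_length.copy()
        bl[self.root] = 0.0
        return float(bl.sum())

    def n_descendant_tips(self) -> np.ndarray:
        """Number of descendant tips below (and including) each node."""
        cnt = np.zeros(self.n_nodes, dtype=np.int64)
        cnt[: self.n_tips] = 1
        for v in self.postorder():
            for c in self.children[v]:
                cnt[v] += cnt[c]
        return cnt

    def subtree_nodes(self, node: int) -> np.ndarray:
        """All nodes in the subtree rooted at ``node`` (inclusive)."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return np.array(out, dtype=np.int64)

    def tip_index(self) -> dict:
        return {lbl: i for i, lbl in enumerate(self.tip_labels)}

    def copy(self) -> "Tree":
        return Tree(
            self.parent.copy(),
            [list(c) for c in self.children],
            self.branch_length.copy(),
            list(self.labels),
            self.n_tips,
        )

    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        dnodes = list(dtree.preorder_node_iter())
        tips = [nd for nd in dnodes if nd.is_leaf()]
        internals = [nd for nd in dnodes if not nd.is_leaf()]
        # root goes last
        internals = [nd for nd in internals[1:]] + [internals[0]] if internals else []
        index = {}
        for i, nd in enumerate(tips):
            index[id(nd)] = i
        for j, nd in enumerate(internals):
            index[id(nd)] = len(tips) + j
        n = len(dnodes)
        parent = np.full(n, -1, dtype=np.int64)
        children = [[] for _ in range(n)]
        blen = np.zeros(n)
        labels = [None] * n
        for nd in dnodes:
            i = index[id(nd)]
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label is not None:
                labels[i] = nd.label
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                blen[i] = float(nd.edge.length) if nd.edge.length is not None else 0.0
        return cls(parent, children, blen, labels, len(tips))

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnode = {self.root: dtree.seed_node}
        for v in self.preorder():
            if v == self.root:
                continue
            p = dnode[self.parent[v]]
            ch = p.new_child()
            ch.edge.length = float(self.branch_length[v])
            dnode[v] = ch
        for i, lbl in enumerate(self.labels):
            if i < self.n_tips:
                dnode[i].taxon = taxa.new_taxon(label=lbl)
        return dtree


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Polytomies are preserved. Raises :class:`TreeError` (with the parser's
    position diagnostics) on malformed input.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"Newick parse error: {exc}") from exc
    return Tree.from_dendropy(dtree)


def write_newick(tree: Tree) -> str:
    """Serialize a tree to Newick with branch lengths (round-trip safe)."""
    dtree = tree.to_dendropy()
    s = io.StringIO()
    dtree.write(
        file=s,
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    )
    return s.getvalue().strip()
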