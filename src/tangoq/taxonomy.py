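"""Reference taxonomy parsing and constant-time ancestor/LCA machinery.

A reference taxonomy is a rooted, multifurcating tree whose leaves carry
the reference sequences (in 16S rRNA surveys, one leaf per annotated
species-level sequence).  Assignment of ambiguous reads needs three tree
primitives to be fast: ancestor tests, lowest-common-ancestor (LCA)
queries, and subtree leaf counts.  :func:`preprocess` computes, in one
left-to-right postorder traversal, a 1-based postorder number ``post`` for
every node and the smallest postorder number ``m`` in its subtree; the
closed interval ``[m, post]`` then contains exactly the postorder numbers
of the subtree, so

    j is a proper ancestor of j'  <=>  m(j) <= m(j') <= post(j') < post(j)

is an O(1) test.  LCA queries are answered in O(1) after O(|T| log |T|)
preprocessing with an Euler tour and a sparse table of range-minimum
depths.
"""

from __future__ import annotations

import math
import os
from functools import reduce
from io import StringIO
from typing import Iterable, List, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

CANONICAL_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


class TaxNode:
    """One node of the taxonomy.

    ``post``, ``m``, ``n_leaves`` and ``depth`` are populated by
    :func:`preprocess`; before that they are ``None`` (``depth`` is set at
    parse time since the parsers build top-down).
    """

    __slots__ = ("id", "name", "rank", "parent", "children", "post", "m",
                 "n_leaves", "depth", "_owner")

    def __init__(self, id: str, name: str, rank: Optional[str] = None,
                 parent: Optional["TaxNode"] = None):
        self.id = id
        self.name = name
        self.rank = rank
        self.parent = parent
        self.children: List[TaxNode] = []
        self.post: Optional[int] = None
        self.m: Optional[int] = None
        self.n_leaves: Optional[int] = None
        self.depth: Optional[int] = None
        self._owner: Optional["TaxonomyIndex"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TaxNode({self.name!r}, rank={self.rank!r}, post={self.post})"


class TaxonomyIndex:
    """A parsed (and optionally preprocessed) reference taxonomy.

    Attributes
    ----------
    nodes : list of TaxNode
        All nodes; after preprocessing, in postorder (``nodes[i].post == i+1``).
    root : TaxNode
    leaf_lookup : dict mapping leaf id -> TaxNode
    rank_scheme : list of rank labels indexed by depth (entry 0 is the root).
    """

    def __init__(self, root: TaxNode, nodes: List[TaxNode]):
        self.root = root
        self.nodes = nodes
        self.leaf_lookup = {}
        for node in nodes:
            node._owner = self
            if node.is_leaf:
                if node.id in self.leaf_lookup:
                    raise ValueError(f"duplicate leaf name: {node.id!r}")
                self.leaf_lookup[node.id] = node
        if not self.leaf_lookup:
            raise ValueError("taxonomy has no leaves")
        self.rank_scheme: List[str] = []
        self.preprocessed = False
        self._euler_nodes: List[TaxNode] = []
        self._euler_depth: Optional[np.ndarray] = None
        self._first: dict = {}
        self._sparse: Optional[np.ndarray] = None
        self._log: Optional[np.ndarray] = None

    @property
    def leaves(self) -> List[TaxNode]:
        return [n for n in self.nodes if n.is_leaf]

    def __len__(self) -> int:
        return len(self.nodes)

    def _check_owned(self, *nodes: TaxNode) -> None:
        for n in nodes:
            if n._owner is not self:
                raise ValueError("node does not belong to this TaxonomyIndex")


def _read_text(source) -> str:
    """Accept a file handle, a path, or literal text (newick/TSV content)."""
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, os.PathLike):
        with open(source) as fh:
            return fh.read()
    if isinstance(source, str):
        looks_like_data = "\n" in source or ";" in source or "\t" in source
        if looks_like_data and not os.path.exists(source):
            return source
        if os.path.exists(source):
            with open(source) as fh:
                return fh.read()
        return source
    raise TypeError(f"cannot read taxonomy from {type(source)!r}")


def _assign_depths_and_ranks(idx: TaxonomyIndex) -> None:
    """Depths by a preorder walk; ranks by depth.

    The seven canonical rank names are applied only when every leaf sits at
    depth 7 (the uniform scheme used by curated 16S taxonomies); otherwise
    generic ``level-k`` labels are used.
    """
    stack = [(idx.root, 0)]
    max_depth = 0
    leaf_depths = set()
    while stack:
        node, d = stack.pop()
        node.depth = d
        max_depth = max(max_depth, d)
        if node.is_leaf:
            leaf_depths.add(d)
        for child in node.children:
            stack.append((child, d + 1))
    if leaf_depths == {7}:
        scheme = ["root"] + list(CANONICAL_RANKS)
    else:
        scheme = ["root"] + [f"level-{d}" for d in range(1, max_depth + 1)]
    idx.rank_scheme = scheme
    for node in idx.nodes:
        if node.rank is None:
            node.rank = scheme[node.depth]


def _parse_newick(text: str) -> TaxonomyIndex:
    try:
        # labels kept as plain node labels so duplicate detection is ours
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True,
                                 suppress_leaf_node_taxa=True)
    except Exception as exc:
        raise ValueError(f"invalid newick: {exc}") from exc
    if tree.seed_node is None or not tree.seed_node.child_nodes():
        raise ValueError("newick taxonomy must have at least one internal node")
    counter = [0]
    nodes: List[TaxNode] = []

    def convert(dnode, parent: Optional[TaxNode]) -> TaxNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        counter[0] += 1
        name = label if label else f"node{counter[0]}"
        node = TaxNode(id=name, name=name, parent=parent)
        nodes.append(node)
        if parent is not None:
            parent.children.append(node)
        for child in dnode.child_nodes():
            convert(child, node)
        return node

    root = convert(tree.seed_node, None)
    idx = TaxonomyIndex(root, nodes)
    _assign_depths_and_ranks(idx)
    return idx


def _parse_lineage_table(text: str) -> TaxonomyIndex:
    df = pd.read_csv(StringIO(text), sep="\t", dtype=str)
    if df.shape[0] == 0:
        raise ValueError("empty lineage table")
    if df.shape[1] < 2:
        raise ValueError("lineage table needs a leaf column plus >= 1 rank column")
    rank_cols = list(df.columns[1:])
    k = len(rank_cols)
    root = TaxNode(id="root", name="root", rank="root")
    root.depth = 0
    nodes = [root]
    by_path: dict = {}
    seen_leaves = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        vals = [None if (isinstance(v, float) and math.isnan(v)) else str(v).strip()
                for v in row]
        if any(v is None or v == "" for v in vals):
            raise ValueError(f"ragged lineage row {row_no}: {vals!r}")
        leaf_id, lineage = vals[0], vals[1:]
        if leaf_id in seen_leaves:
            raise ValueError(f"duplicate leaf name: {leaf_id!r} (row {row_no})")
        seen_leaves.add(leaf_id)
        parent = root
        for depth, name in enumerate(lineage[:-1], start=1):
            key = tuple(lineage[:depth])
            node = by_path.get(key)
            if node is None:
                node = TaxNode(id=name, name=name, rank=rank_cols[depth - 1], parent=parent)
                node.depth = depth
                parent.children.append(node)
                by_path[key] = node
                nodes.append(node)
            elif node.parent is not parent:
                raise ValueError(f"inconsistent lineage at row {row_no}: {name!r}")
            parent = node
        leaf = TaxNode(id=leaf_id, name=lineage[-1], rank=rank_cols[-1], parent=parent)
        leaf.depth = k
        parent.children.append(leaf)
        nodes.append(leaf)
    idx = TaxonomyIndex(root, nodes)
    idx.rank_scheme = ["root"] + rank_cols
    return idx


def parse_taxonomy(source, format: str = "newick") -> TaxonomyIndex:
    """Parse a reference taxonomy from Newick or a rank-lineage table.

    Parameters
    ----------
    source : path, file handle, or literal text.
    format : ``"newick"`` or ``"lineage_table"``.

    The returned index is *not* preprocessed; call :func:`preprocess`
    before using ancestor/LCA queries.
    """
    text = _read_text(source).strip()
    if not text:
        raise ValueError("empty taxonomy input")
    if format == "newick":
        return _parse_newick(text)
    if format == "lineage_table":
        return _parse_lineage_table(text)
    raise ValueError(f"unknown taxonomy format: {format!r}")


def preprocess(idx: TaxonomyIndex) -> TaxonomyIndex:
    """Populate post/m/n_leaves/depth and build the O(1)-LCA index.

    Runs in O(|T| log |T|) and is idempotent: re-running reproduces the
    identical numbering (child order is fixed by the input file).
    """
    # Iterative left-to-right postorder numbering.
    order: List[TaxNode] = []
    stack: List[tuple] = [(idx.root, iter(idx.root.children))]
    idx.root.depth = 0
    post = 0
    while stack:
        node, it = stack[-1]
        child = next(it, None)
        if child is not None:
            child.depth = node.depth + 1
            stack.append((child, iter(child.children)))
            continue
        stack.pop()
        post += 1
        node.post = post
        if node.is_leaf:
            node.m = post
            node.n_leaves = 1
        else:
            node.m = min(c.m for c in node.children)
            node.n_leaves = sum(c.n_leaves for c in node.children)
        order.append(node)
    idx.nodes = order

    # Euler tour of the tree for range-minimum LCA queries.
    euler: List[TaxNode] = []
    depths: List[int] = []
    first: dict = {}
    stack2: List[tuple] = [(idx.root, iter(idx.root.children))]
    euler.append(idx.root)
    depths.append(0)
    first[idx.root] = 0
    while stack2:
        node, it = stack2[-1]
        child = next(it, None)
        if child is None:
            stack2.pop()
            if stack2:
                parent = stack2[-1][0]
                euler.append(parent)
                depths.append(parent.depth)
            continue
        euler.append(child)
        depths.append(child.depth)
        first.setdefault(child, len(euler) - 1)
        stack2.append((child, iter(child.children)))

    d = np.asarray(depths, dtype=np.int64)
    n = len(d)
    log = np.zeros(n + 1, dtype=np.int64)
    for i in range(2, n + 1):
        log[i] = log[i // 2] + 1
    kmax = int(log[n]) + 1
    sparse = np.empty((kmax, n), dtype=np.int64)
    sparse[0] = np.arange(n)
    for k in range(1, kmax):
        span = 1 << k
        half = span >> 1
        width = n - span + 1
        if width <= 0:
            sparse[k] = sparse[k - 1]
            continue
        left = sparse[k - 1, :width]
        right = sparse[k - 1, half:half + width]
        take_left = d[left] <= d[right]
        sparse[k, :width] = np.where(take_left, left, right)
        sparse[k, width:] = sparse[k - 1, width:]

    idx._euler_nodes = euler
    idx._euler_depth = d
    idx._first = first
    idx._sparse = sparse
    idx._log = log
    idx.preprocessed = True
    return idx


def _require_preprocessed(idx: TaxonomyIndex) -> None:
    if not idx.preprocessed:
        raise ValueError("TaxonomyIndex is not preprocessed; call preprocess() first")


def is_proper_ancestor(idx: TaxonomyIndex, j: TaxNode, j2: TaxNode) -> bool:
    """O(1) test that ``j`` is a proper ancestor of ``j2``.

    Uses the postorder-interval characterization
    m(j) <= m(j') <= post(j') < post(j).
    """
    _require_preprocessed(idx)
    idx._check_owned(j, j2)
    return j.m <= j2.m <= j2.post < j.post


def lca(idx: TaxonomyIndex, u: TaxNode, v: TaxNode) -> TaxNode:
    """O(1) lowest common ancestor via Euler tour + sparse table."""
    _require_preprocessed(idx)
    idx._check_owned(u, v)
    if u is v:
        return u
    l, r = idx._first[u], idx._first[v]
    if l > r:
        l, r = r, l
    k = int(idx._log[r - l + 1])
    span = 1 << k
    a = int(idx._sparse[k, l])
    b = int(idx._sparse[k, r - span + 1])
    pos = a if idx._euler_depth[a] <= idx._euler_depth[b] else b
    return idx._euler_nodes[pos]


def lca_of_set(idx: TaxonomyIndex, leaves: Iterable[TaxNode]) -> TaxNode:
    """LCA of a non-empty set of nodes (fold of pairwise LCA)."""
    leaves = list(leaves)
    if not leaves:
        raise ValueError("lca_of_set: empty set")
    return reduce(lambda a, b: lca(idx, a, b), leaves)


def subtree_nodes(node: TaxNode) -> List[TaxNode]:
    """All nodes of the subtree rooted at ``node`` (iterative DFS)."""
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def to_newick(idx: TaxonomyIndex) -> str:
    """Serialize the taxonomy to Newick (internal labels kept)."""

    def render(node: TaxNode) -> str:
        if node.is_leaf:
            return node.id
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){node.name}"

    return render(idx.root) + ";\n"


def to_lineage_table(idx: TaxonomyIndex) -> str:
    """Serialize a uniform-depth taxonomy to the rank-lineage TSV format."""
    leaves = idx.leaves
    depths = set()
    rows = []
    for leaf in leaves:
        path = []
        node = leaf
        while node.parent is not None:
            path.append(node)
            node = node.parent
        path.reverse()
        depths.add(len(path))
        rows.append([leaf.id] + [n.name for n in path])
    if len(depths) != 1:
        raise ValueError("lineage table export requires uniform leaf depth")
    k = depths.pop()
    if len(idx.rank_scheme) == k + 1:
        header = ["leaf"] + list(idx.rank_scheme[1:])
    else:
        header = ["leaf"] + [f"level{i}" for i in range(1, k + 1)]
    lines = ["\t".join(header)]
    lines.extend("\t".join(r) for r in rows)
    return "\n".join(lines) + "\n"
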