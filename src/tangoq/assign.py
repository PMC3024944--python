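"""Penalty-score assignment of ambiguous reads to taxonomy nodes.

An ambiguous read matches a set of leaves ``M_i``.  Let ``T_i`` be the
subtree rooted at the LCA of ``M_i``.  Choosing a candidate node ``j`` of
``T_i`` partitions the leaves of ``T_i`` into

    TP = hits under j,  FP = non-hits under j,
    FN = hits outside j, TN = non-hits outside j,

and the penalty score with respect to a weight ``q`` in [0, 1] is

    PS(j) = q * |FN|/|TP| + (1 - q) * |FP|/|TP|        (infinity if |TP| = 0)

``q = 1`` recovers classical LCA assignment (PS = 0 at the LCA), ``q = 0``
admits an optimal assignment at a hit leaf, and ``q = 0.5`` is equivalent
to maximizing the F-measure.  The read is assigned to the node(s) of
minimum penalty.

Two algorithms are provided: :func:`assign_naive` scores every node of
``T_i`` via two traversals (O(|T_i|)), and :func:`assign_fast` scores only
the *relevant* nodes — hit leaves and pairwise LCAs of hits — which always
contain a minimizer, using the topological restriction ``T_i || M_i`` with
O(|M_i|) nodes.  Scores are exact rationals so tie sets are stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Dict, Iterable, List, Optional, Sequence, Union

from .hits import HitSet
from .taxonomy import (TaxNode, TaxonomyIndex, is_proper_ancestor, lca,
                       lca_of_set, subtree_nodes)

Score = Union[Fraction, float]  # exact rational, or math.inf

DEFAULT_Q_GRID = tuple(Fraction(i, 10) for i in range(11))


def as_q_fraction(q) -> Fraction:
    """Validate q in [0, 1] and convert to an exact rational.

    Floats are snapped to the nearest rational with denominator <= 10^6
    (grid values like 0.1 become exactly 1/10), so tie sets do not depend
    on binary rounding.
    """
    if isinstance(q, float):
        if math.isnan(q):
            raise ValueError("q must be in [0, 1]")
        qf = Fraction(q).limit_denominator(10 ** 6)
    elif isinstance(q, Rational):
        qf = Fraction(q)
    else:
        raise TypeError(f"q must be a real number, got {type(q)!r}")
    if not 0 <= qf <= 1:
        raise ValueError(f"q must be in [0, 1], got {q!r}")
    return qf


@dataclass(frozen=True)
class ConfusionCounts:
    """Leaf-partition sizes of ``T_i`` for one candidate node."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def f_measure(self) -> Fraction:
        denom = self.fn + self.fp + 2 * self.tp
        return Fraction(2 * self.tp, denom) if denom else Fraction(0)


@dataclass
class Assignment:
    """Result of assigning one read at one value of q.

    ``best_nodes`` is the full tie set of minimum-penalty nodes;
    ``canonical_node`` is the deterministic representative (fewest subtree
    leaves, then smallest postorder number).  Unassigned reads (empty hit
    set) have ``canonical_node is None`` and infinite score.
    """

    read_id: str
    q: float
    best_nodes: List[TaxNode]
    canonical_node: Optional[TaxNode]
    score: Score
    counts: Optional[ConfusionCounts]
    rank: Optional[str]

    @property
    def assigned(self) -> bool:
        return self.canonical_node is not None

    @property
    def n_ties(self) -> int:
        return len(self.best_nodes)


@dataclass
class RestrictedTree:
    """The topological restriction ``T_i || M_i``: hit leaves plus LCAs of
    adjacent hits (in postorder), with parent links within the restriction
    and per-node hit counts ``|M_{i,j}|``.  Has at most 2|M_i| - 1 nodes.
    """

    nodes: List[TaxNode]
    parent: Dict[TaxNode, Optional[TaxNode]]
    root: TaxNode
    m_count: Dict[TaxNode, int]


def penalty_score(c: ConfusionCounts, q) -> Score:
    """Evaluate the penalty score for one candidate node.

    Returns an exact :class:`fractions.Fraction`, or ``math.inf`` when
    ``tp == 0``.
    """
    qf = as_q_fraction(q)
    if c.tp == 0:
        return math.inf
    return qf * Fraction(c.fn, c.tp) + (1 - qf) * Fraction(c.fp, c.tp)


def _score(tp: int, fp: int, fn: int, qf: Fraction) -> Score:
    if tp == 0:
        return math.inf
    return (qf * fn + (1 - qf) * fp) / tp


def _finish(read_id: str, q, scored: List[tuple], li_total: int,
            n_hits: int) -> Assignment:
    """Pick the minimum-score tie set and the canonical representative.

    ``scored`` holds (node, tp, score) triples; tie-break is (fewest
    subtree leaves, smallest postorder number).
    """
    best: Score = math.inf
    for _, _, s in scored:
        if s < best:
            best = s
    ties = [(node, tp) for node, tp, s in scored if s == best]
    ties.sort(key=lambda t: (t[0].n_leaves, t[0].post))
    canonical, tp = ties[0]
    fn = n_hits - tp
    fp = canonical.n_leaves - tp
    tn = li_total - canonical.n_leaves - fn
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return Assignment(read_id=read_id, q=float(q), best_nodes=[n for n, _ in ties],
                      canonical_node=canonical, score=best, counts=counts,
                      rank=canonical.rank)


def assign_naive(idx: TaxonomyIndex, m: HitSet, q) -> Assignment:
    """Score every node of ``T_i`` by two traversals (bottom-up to find the
    LCA root, top-down/postorder to accumulate the counts recursively).

    Works on O(|T_i|) nodes; kept as the reference algorithm against which
    :func:`assign_fast` is checked.
    """
    qf = as_q_fraction(q)
    if len(m.hits) < 2:
        raise ValueError("assign_naive requires an ambiguous read (>= 2 hits)")
    idx._check_owned(*m.hits)
    hit_set = set(m.hits)
    n_hits = len(hit_set)

    # Bottom-up traversal: count descendant hits along ancestor chains; the
    # lowest node covering all of M_i is the root of T_i.
    counts: Dict[TaxNode, int] = {}
    for h in hit_set:
        node: Optional[TaxNode] = h
        while node is not None:
            counts[node] = counts.get(node, 0) + 1
            node = node.parent
    root = m.hits[0]
    while counts.get(root, 0) < n_hits:
        root = root.parent

    # Postorder over T_i applying the recursive relations for |M_{i,j}|
    # and |L_{i,j}| (leaf in M_i -> (1,1); leaf not in M_i -> (0,1)).
    m_ij: Dict[TaxNode, int] = {}
    l_ij: Dict[TaxNode, int] = {}
    order: List[TaxNode] = []
    stack = [(root, iter(root.children))]
    while stack:
        node, it = stack[-1]
        child = next(it, None)
        if child is not None:
            stack.append((child, iter(child.children)))
            continue
        stack.pop()
        if node.is_leaf:
            in_m = node in hit_set
            m_ij[node] = 1 if in_m else 0
            l_ij[node] = 1
        else:
            m_ij[node] = sum(m_ij[c] for c in node.children)
            l_ij[node] = sum(l_ij[c] for c in node.children)
        order.append(node)

    li_total = l_ij[root]
    scored = []
    for node in order:
        tp = m_ij[node]
        fp = l_ij[node] - tp
        fn = n_hits - tp
        scored.append((node, tp, _score(tp, fp, fn, qf)))
    # local postorder rank equals global postorder restricted to T_i; make
    # the tie-break usable even on unpreprocessed trees
    if not idx.preprocessed:
        local_post = {node: i + 1 for i, node in enumerate(order)}
        for node in order:
            if node.post is None:
                node.post = local_post[node]
                node.n_leaves = l_ij[node]
    return _finish(m.read_id, q, scored, li_total, n_hits)


def build_restriction(idx: TaxonomyIndex, m: HitSet) -> RestrictedTree:
    """Build ``T_i || M_i`` in O(|M_i|) tree operations.

    Sort the hits by postorder number; the relevant nodes are the hits plus
    the LCAs of postorder-adjacent pairs.  Sorting the relevant nodes by
    (m(j) ascending, post(j) descending) places every ancestor before its
    descendants, so a single stack sweep recovers the parent links.
    """
    if not idx.preprocessed:
        raise ValueError("build_restriction requires a preprocessed index")
    if len(m.hits) < 2:
        raise ValueError("build_restriction requires >= 2 hits")
    idx._check_owned(*m.hits)
    leaves = sorted(set(m.hits), key=lambda n: n.post)
    u: Dict[TaxNode, None] = dict.fromkeys(leaves)
    for a, b in zip(leaves, leaves[1:]):
        u.setdefault(lca(idx, a, b), None)
    nodes = sorted(u, key=lambda n: (n.m, -n.post))

    parent: Dict[TaxNode, Optional[TaxNode]] = {}
    anc_stack: List[TaxNode] = []
    for node in nodes:
        while anc_stack and not (anc_stack[-1].m <= node.m <= node.post < anc_stack[-1].post):
            anc_stack.pop()
        parent[node] = anc_stack[-1] if anc_stack else None
        anc_stack.append(node)
    root = nodes[0]

    hit_set = set(leaves)
    m_count = {n: (1 if n in hit_set else 0) for n in nodes}
    for node in sorted(nodes, key=lambda n: n.post):
        p = parent[node]
        if p is not None:
            m_count[p] += m_count[node]
    return RestrictedTree(nodes=nodes, parent=parent, root=root, m_count=m_count)


def assign_fast(idx: TaxonomyIndex, m: HitSet, q) -> Assignment:
    """Score only the relevant nodes of ``T_i`` (O(|M_i|) after
    preprocessing).  A relevant node always attains the minimum penalty, so
    the minimum *score* equals :func:`assign_naive`'s; non-relevant
    co-minimizers are deliberately not enumerated.
    """
    qf = as_q_fraction(q)
    rt = build_restriction(idx, m)
    n_hits = len(set(m.hits))
    li_total = rt.root.n_leaves
    scored = []
    for node in rt.nodes:
        tp = rt.m_count[node]
        fp = node.n_leaves - tp  # |N_{i,j}| = |L_j| - |M_{i,j}|, |L_j| precomputed
        fn = n_hits - tp
        scored.append((node, tp, _score(tp, fp, fn, qf)))
    return _finish(m.read_id, q, scored, li_total, n_hits)


def assign_read(idx: TaxonomyIndex, m: HitSet, q) -> Assignment:
    """Dispatch on hit-set size: empty -> unassigned marker; singleton ->
    that leaf with score 0; ambiguous -> :func:`assign_fast`.
    """
    as_q_fraction(q)
    if len(m.hits) == 0:
        return Assignment(read_id=m.read_id, q=float(q), best_nodes=[],
                          canonical_node=None, score=math.inf, counts=None,
                          rank=None)
    if len(m.hits) == 1:
        leaf = m.hits[0]
        idx._check_owned(leaf)
        counts = ConfusionCounts(tp=1, fp=0, tn=0, fn=0)
        return Assignment(read_id=m.read_id, q=float(q), best_nodes=[leaf],
                          canonical_node=leaf, score=Fraction(0), counts=counts,
                          rank=leaf.rank)
    return assign_fast(idx, m, q)


def sweep_q(idx: TaxonomyIndex, hitsets: Sequence[HitSet],
            q_grid: Optional[Sequence] = None) -> List[Assignment]:
    """One assignment per read per q (default grid 0.0, 0.1, ..., 1.0)."""
    grid = DEFAULT_Q_GRID if q_grid is None else list(q_grid)
    return [assign_read(idx, m, q) for q in grid for m in hitsets]


def rank_distribution(assignments: Sequence[Assignment]):
    """Count assigned reads per (rank, q); unassigned reads are excluded
    from the matrix and reported separately.

    Returns ``(counts, unassigned)`` — a rank x q DataFrame (ranks ordered
    by the taxonomy's depth scheme where possible) and a per-q Series of
    unassigned-read counts.
    """
    import pandas as pd

    qs = sorted({round(a.q, 6) for a in assignments})
    assigned = [a for a in assignments if a.assigned]
    rank_order: List[str] = []
    for a in assigned:
        if a.rank not in rank_order:
            rank_order.append(a.rank)
    owner = assigned[0].canonical_node._owner if assigned else None
    if owner is not None and owner.rank_scheme:
        scheme = [r for r in owner.rank_scheme if r in set(rank_order)]
        scheme += [r for r in rank_order if r not in scheme]
        rank_order = scheme
    counts = pd.DataFrame(0, index=rank_order, columns=qs, dtype=int)
    unassigned = pd.Series(0, index=qs, dtype=int)
    for a in assignments:
        qkey = round(a.q, 6)
        if a.assigned:
            counts.loc[a.rank, qkey] += 1
        else:
            unassigned[qkey] += 1
    counts.index.name = "rank"
    counts.columns.name = "q"
    return counts, unassigned
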