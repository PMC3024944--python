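"""ROC-space validation of penalty-score assignments on data with known truth.

For simulated reads the true source leaf ``H_i`` is known, so each
assignment can be scored against the *singleton* truth set {H_i} inside
``T_i`` (the subtree rooted at the LCA of the hits).  The true positive
rate is 1 exactly when H_i lies under the assigned node; the false
positive rate is the fraction of the other |L_i| - 1 leaves of T_i that
lie under it.  Each read becomes a point (FPR_H, TPR_H) in ROC space and
its signed distance to the no-skill diagonal is

    D = (sqrt(2)/2) * (|L_i| - |L_i,j|) / (|L_i| - 1)        if H under j
    D = -(sqrt(2)/2) * (|L_i| - |L_i,j| - 1) / (|L_i| - 1)   otherwise

(the second formula is implemented exactly as printed in the method's
description; note it is not the geometric point-to-diagonal distance of
(FPR, 0), which would be (sqrt(2)/2) * FPR — see docs/methods.md).

Summing D over reads gives the goodness ``G_q`` of a fixed q.  Without
truth, the *expected* distance uses p = |M_{i,j}|/|M_i| as the probability
that H lies under j; maximizing it per read over a q grid gives the
per-read best-q rule (fall back to the LCA when no candidate has positive
expected distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .assign import DEFAULT_Q_GRID, Assignment, assign_read
from .hits import HitSet
from .taxonomy import TaxNode, TaxonomyIndex, lca_of_set

SQRT2_OVER_2 = math.sqrt(2.0) / 2.0


@dataclass
class RocRecord:
    """Truth-based confusion and ROC geometry for one assigned read.

    ``valid`` is False for degenerate reads (|M_i| < 2 or |L_i| = 1),
    which are excluded from all sums but counted.
    """

    read_id: str
    h_in_subtree: bool
    tpr_h: int
    fpr_h: float
    l_i: int
    l_ij: int
    d: Optional[float] = None
    valid: bool = True


@dataclass
class ExpectedDistance:
    """Truth-free expected signed distance for assigning a read to a node."""

    read_id: str
    node: TaxNode
    p: float
    e_d: float
    valid: bool = True


def _node_contains(idx: TaxonomyIndex, node: TaxNode, leaf: TaxNode) -> bool:
    return node.m <= leaf.post <= node.post


def truth_confusion(idx: TaxonomyIndex, m: HitSet, node: TaxNode) -> RocRecord:
    """Singleton-truth confusion of assigning read ``m`` to ``node``.

    TPR_H is 1 iff H_i lies in the subtree of ``node`` (0 when the matcher
    missed the truth entirely, i.e. H_i outside T_i);
    FPR_H = (|L_i,j| - TPR_H) / (|L_i| - 1).
    """
    if m.true_hit is None:
        raise ValueError(f"read {m.read_id!r} has no known true hit")
    idx._check_owned(node, m.true_hit)
    root = lca_of_set(idx, m.hits)
    l_i = root.n_leaves
    l_ij = node.n_leaves
    h_in = _node_contains(idx, node, m.true_hit)
    tpr = 1 if h_in else 0
    valid = l_i > 1 and len(m.hits) >= 2
    fpr = (l_ij - tpr) / (l_i - 1) if l_i > 1 else math.nan
    return RocRecord(read_id=m.read_id, h_in_subtree=h_in, tpr_h=tpr,
                     fpr_h=fpr, l_i=l_i, l_ij=l_ij, valid=valid)


def roc_distance(rec: RocRecord) -> float:
    """Signed distance of the read's ROC point to the diagonal (as printed;
    positive iff H lies under the assigned node).  |D| <= sqrt(2)/2.
    """
    if rec.l_i <= 1:
        raise ValueError("degenerate T_i (single leaf): distance undefined")
    if rec.h_in_subtree:
        return SQRT2_OVER_2 * (rec.l_i - rec.l_ij) / (rec.l_i - 1)
    return -SQRT2_OVER_2 * (rec.l_i - rec.l_ij - 1) / (rec.l_i - 1)


def roc_record(idx: TaxonomyIndex, m: HitSet, node: TaxNode) -> RocRecord:
    """Convenience: :func:`truth_confusion` with the distance filled in."""
    rec = truth_confusion(idx, m, node)
    if rec.valid:
        rec.d = roc_distance(rec)
    return rec


def goodness_gq(records: Sequence[RocRecord]) -> float:
    """G_q: sum of signed distances over valid reads for one fixed q."""
    return float(sum(r.d for r in records if r.valid and r.d is not None))


def expected_distance(idx: TaxonomyIndex, m: HitSet, node: TaxNode) -> ExpectedDistance:
    """Expected signed distance without truth: weight the in/out distances
    by p = |M_{i,j}| / |M_i|, the fraction of hits under the node.
    """
    if len(m.hits) < 2:
        raise ValueError("expected_distance requires an ambiguous read")
    idx._check_owned(node, *m.hits)
    root = lca_of_set(idx, m.hits)
    l_i = root.n_leaves
    l_ij = node.n_leaves
    m_ij = sum(1 for h in set(m.hits) if _node_contains(idx, node, h))
    p = m_ij / len(set(m.hits))
    if l_i <= 1:
        return ExpectedDistance(read_id=m.read_id, node=node, p=p, e_d=math.nan,
                                valid=False)
    d_in = SQRT2_OVER_2 * (l_i - l_ij) / (l_i - 1)
    d_out = -SQRT2_OVER_2 * (l_i - l_ij - 1) / (l_i - 1)
    return ExpectedDistance(read_id=m.read_id, node=node, p=p,
                            e_d=p * d_in + (1.0 - p) * d_out)


def best_q_per_read(idx: TaxonomyIndex, m: HitSet,
                    q_grid: Optional[Sequence] = None) -> Tuple[TaxNode, float, float]:
    """Per-read rule: evaluate the expected distance at the canonical node
    for each q in the grid and pick the maximizer; if no candidate has a
    positive expected distance, prefer the LCA (q = 1).

    Returns ``(node, q, e_d)``.
    """
    if len(m.hits) < 2:
        raise ValueError("best_q_per_read requires an ambiguous read")
    grid = DEFAULT_Q_GRID if q_grid is None else list(q_grid)
    best_node = None
    best_q = None
    best_ed = -math.inf
    for q in grid:
        a = assign_read(idx, m, q)
        ed = expected_distance(idx, m, a.canonical_node)
        if not ed.valid:
            continue
        if ed.e_d > best_ed:
            best_node, best_q, best_ed = a.canonical_node, float(q), ed.e_d
    if best_node is None or best_ed <= 0:
        root = lca_of_set(idx, m.hits)
        ed0 = expected_distance(idx, m, root)
        return root, 1.0, ed0.e_d if ed0.valid else 0.0
    return best_node, best_q, best_ed


def precision_recall_truth(records: Sequence[RocRecord]) -> Tuple[float, float]:
    """Unweighted means over valid ambiguous reads of the singleton-truth
    precision (TPR_H / |L_i,j|) and recall (TPR_H).
    """
    valid = [r for r in records if r.valid]
    if not valid:
        return math.nan, math.nan
    precision = sum(r.tpr_h / r.l_ij for r in valid) / len(valid)
    recall = sum(r.tpr_h for r in valid) / len(valid)
    return precision, recall


def per_q_validation(idx: TaxonomyIndex, hitsets: Sequence[HitSet],
                     q_grid: Optional[Sequence] = None
                     ) -> Tuple[pd.DataFrame, Dict[float, List[RocRecord]]]:
    """Evaluate a q grid on a truth-bearing dataset.

    Returns a per-q table (n reads, G_q, mean distance, mean precision,
    mean recall) and the underlying per-q RocRecords for downstream paired
    analyses.  Only ambiguous reads with non-degenerate T_i contribute.
    """
    grid = DEFAULT_Q_GRID if q_grid is None else list(q_grid)
    ambiguous = [m for m in hitsets if m.is_ambiguous and m.true_hit is not None]
    rows = []
    per_q: Dict[float, List[RocRecord]] = {}
    for q in grid:
        recs = []
        for m in ambiguous:
            a = assign_read(idx, m, q)
            recs.append(roc_record(idx, m, a.canonical_node))
        valid = [r for r in recs if r.valid]
        p, r = precision_recall_truth(recs)
        gq = goodness_gq(recs)
        rows.append({"q": float(q), "n": len(valid), "G_q": gq,
                     "mean_D": gq / len(valid) if valid else math.nan,
                     "precision": p, "recall": r})
        per_q[float(q)] = recs
    return pd.DataFrame(rows), per_q


def best_q_validation(idx: TaxonomyIndex, hitsets: Sequence[HitSet],
                      q_grid: Optional[Sequence] = None) -> pd.DataFrame:
    """Apply the per-read best-q rule; realized distances where truth is known.

    Returns one row per ambiguous read: chosen q, chosen node, expected
    distance, and (when the true hit is recorded) the realized signed
    distance of the chosen assignment.
    """
    rows = []
    for m in hitsets:
        if not m.is_ambiguous:
            continue
        node, q, ed = best_q_per_read(idx, m, q_grid)
        row = {"read_id": m.read_id, "chosen_q": q, "node": node.name,
               "rank": node.rank, "e_d": ed, "d": math.nan}
        if m.true_hit is not None:
            rec = roc_record(idx, m, node)
            if rec.valid:
                row["d"] = rec.d
        rows.append(row)
    return pd.DataFrame(rows)
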