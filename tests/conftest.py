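"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's fast paths: LCA and
ancestor tests are done by parent walks, and penalty scores / F-measures
are recomputed from explicitly enumerated leaf sets over the whole tree.
"""

import math
from fractions import Fraction

import numpy as np
import pytest

import tangoq as tq

# Tree realizing the worked-example partition: the node f2 has leaf set
# {s5,s6,s7,s8}; with hits {s1,s5,s6,s7} it yields TP={s5,s6,s7}, FP={s8},
# TN={s2,s3,s4}, FN={s1}.
FIG1_NEWICK = "(((s1,s2)g1,(s3,s4)g2)f1,((s5,s6,s7)g3,s8)f2)root;"
FIG1_HITS = ("s1", "s5", "s6", "s7")


@pytest.fixture(scope="session")
def fig1_index():
    return tq.preprocess(tq.parse_taxonomy(FIG1_NEWICK))


@pytest.fixture()
def fig1_hitset(fig1_index):
    idx = fig1_index
    return tq.HitSet("r1", tuple(idx.leaf_lookup[s] for s in FIG1_HITS),
                     true_hit=idx.leaf_lookup["s5"])


# ---------------------------------------------------------------- oracles


def walk_ancestors(node):
    """Node and all its ancestors, bottom-up."""
    out = []
    while node is not None:
        out.append(node)
        node = node.parent
    return out


def walk_is_proper_ancestor(a, b):
    return a is not b and a in walk_ancestors(b)


def walk_lca(u, v):
    anc = set(walk_ancestors(u))
    node = v
    while node not in anc:
        node = node.parent
    return node


def walk_lca_set(nodes):
    nodes = list(nodes)
    out = nodes[0]
    for n in nodes[1:]:
        out = walk_lca(out, n)
    return out


def leaf_sets(root):
    """Explicit frozenset of descendant leaves for every node under root."""
    sets = {}

    def rec(node):
        if not node.children:
            sets[node] = frozenset([node])
        else:
            acc = frozenset()
            for c in node.children:
                rec(c)
                acc |= sets[c]
            sets[node] = acc
        return sets[node]

    rec(root)
    return sets


def brute_force_scores(idx, hits, q):
    """Penalty score of every node of T_i by explicit leaf-set enumeration.

    Independent of the package's count recursions and restriction
    machinery; exact rational arithmetic.
    """
    qf = Fraction(q).limit_denominator(10 ** 6)
    m_set = frozenset(hits)
    root_ti = walk_lca_set(hits)
    sets = leaf_sets(root_ti)
    scores = {}
    for node, leaves in sets.items():
        tp = len(leaves & m_set)
        fp = len(leaves - m_set)
        fn = len(m_set - leaves)
        if tp == 0:
            scores[node] = math.inf
        else:
            scores[node] = qf * Fraction(fn, tp) + (1 - qf) * Fraction(fp, tp)
    return scores


def brute_force_best(idx, hits, q):
    scores = brute_force_scores(idx, hits, q)
    best = min(scores.values())
    return best, {n for n, s in scores.items() if s == best}


def brute_force_f_argmax(idx, hits):
    """Nodes of T_i maximizing the F-measure, from enumerated leaf sets."""
    m_set = frozenset(hits)
    root_ti = walk_lca_set(hits)
    sets = leaf_sets(root_ti)
    fvals = {}
    for node, leaves in sets.items():
        tp = len(leaves & m_set)
        fp = len(leaves - m_set)
        fn = len(m_set - leaves)
        fvals[node] = Fraction(2 * tp, fn + fp + 2 * tp)
    best = max(fvals.values())
    return {n for n, f in fvals.items() if f == best}


def random_instance(seed, max_leaves=200, max_hits=40):
    """A random ranked taxonomy plus a random ambiguous hit set."""
    rng = np.random.default_rng(seed)
    n_leaves = int(rng.integers(10, max_leaves + 1))
    idx = tq.random_taxonomy(int(rng.integers(0, 2 ** 31)), n_leaves)
    leaves = idx.leaves
    size = int(rng.integers(2, min(max_hits, n_leaves) + 1))
    picked = rng.choice(len(leaves), size=size, replace=False)
    hits = tuple(leaves[i] for i in picked)
    return idx, tq.HitSet(f"read{seed}", hits)


Q_GRID = [Fraction(i, 10) for i in range(11)]


@pytest.fixture(scope="session")
def synthetic_datasets():
    """Five seeded end-to-end datasets (taxonomy, references, reads matched
    at k=2 with truth attached); shared by the statistical tests."""
    out = []
    for seed in (1, 2, 3, 4, 5):
        cfg = tq.SimConfig(seed=seed)
        idx, seqs, reads, truth, hitsets = tq.simulate_dataset(cfg, k=2)
        out.append((cfg, idx, seqs, reads, truth, hitsets))
    return out
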