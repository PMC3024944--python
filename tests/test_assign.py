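"""Penalty scores, naive vs relevant-node assignment, restrictions, sweeps."""

import math
from fractions import Fraction

import numpy as np
import pytest

import tangoq as tq
from conftest import (Q_GRID, brute_force_best, brute_force_f_argmax,
                      random_instance, walk_is_proper_ancestor, walk_lca,
                      walk_lca_set)


class TestPenaltyScore:
    def test_worked_example_is_one_third_for_every_q(self):
        # TP={s5,s6,s7}, FP={s8}, TN={s2,s3,s4}, FN={s1}
        c = tq.ConfusionCounts(tp=3, fp=1, tn=3, fn=1)
        for q in Q_GRID:
            assert tq.penalty_score(c, q) == Fraction(1, 3)

    def test_lca_counts_give_zero_at_q1(self):
        c = tq.ConfusionCounts(tp=4, fp=4, tn=0, fn=0)
        assert tq.penalty_score(c, 1.0) == 0
        assert tq.penalty_score(c, 0.25) == Fraction(3, 4)  # (1-q)*fp/tp

    def test_zero_tp_is_infinite(self):
        assert tq.penalty_score(tq.ConfusionCounts(0, 3, 2, 4), 0.5) == math.inf

    @pytest.mark.parametrize("q", [-0.1, 1.5, float("nan")])
    def test_q_outside_unit_interval_rejected(self, q):
        with pytest.raises(ValueError):
            tq.penalty_score(tq.ConfusionCounts(1, 0, 0, 0), q)


class TestAssignBoundaries:
    def test_q1_assigns_lca_with_zero_score(self, fig1_index, fig1_hitset):
        a = tq.assign_fast(fig1_index, fig1_hitset, 1.0)
        assert a.canonical_node is fig1_index.root
        assert a.score == 0
        assert a.counts.fn == 0

    def test_q0_assigns_a_hit_leaf_with_zero_score(self, fig1_index, fig1_hitset):
        a = tq.assign_fast(fig1_index, fig1_hitset, 0.0)
        assert a.score == 0
        assert a.canonical_node in fig1_hitset.hits
        b = tq.assign_naive(fig1_index, fig1_hitset, 0.0)
        assert b.score == 0
        assert any(n in fig1_hitset.hits for n in b.best_nodes)

    def test_boundaries_on_random_instances(self):
        for seed in range(25):
            idx, m = random_instance(seed, max_leaves=80, max_hits=12)
            root_ti = walk_lca_set(m.hits)
            a1 = tq.assign_fast(idx, m, 1.0)
            assert a1.score == 0 and a1.canonical_node is root_ti
            a0 = tq.assign_fast(idx, m, 0.0)
            assert a0.score == 0 and a0.canonical_node in set(m.hits)

    def test_lca_closed_form(self):
        # PS at the LCA is (1-q)*(|L_i|-|M_i|)/|M_i| exactly
        for seed in range(15):
            idx, m = random_instance(seed, max_leaves=80, max_hits=12)
            root_ti = walk_lca_set(m.hits)
            n_m = len(set(m.hits))
            for q in (0.0, 0.3, 0.7, 1.0):
                qf = Fraction(q).limit_denominator(10 ** 6)
                expected = (1 - qf) * Fraction(root_ti.n_leaves - n_m, n_m)
                got = tq.penalty_score(_counts_at(idx, m, root_ti), q)
                assert got == expected


def _counts_at(idx, m, node):
    """Confusion counts at a node from first principles (interval test)."""
    m_set = set(m.hits)
    root_ti = walk_lca_set(m.hits)
    under = lambda n, leaf: n.m <= leaf.post <= n.post
    tp = sum(1 for h in m_set if under(node, h))
    l_ij = node.n_leaves
    fp = l_ij - tp
    fn = len(m_set) - tp
    tn = root_ti.n_leaves - l_ij - fn
    return tq.ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


class TestRestriction:
    def test_two_hits_give_cherry(self, fig1_index):
        idx = fig1_index
        m = tq.HitSet("r", (idx.leaf_lookup["s1"], idx.leaf_lookup["s5"]))
        rt = tq.build_restriction(idx, m)
        assert len(rt.nodes) == 3
        assert rt.root is idx.root
        assert rt.m_count[rt.root] == 2

    def test_all_leaves_of_binary_tree_recover_tree(self):
        idx = tq.preprocess(tq.parse_taxonomy("(((a,b)x,(c,d)y)u,((e,f)z,g)v)r;"))
        m = tq.HitSet("r", tuple(idx.leaves))
        rt = tq.build_restriction(idx, m)
        assert set(rt.nodes) == set(idx.nodes)
        for node in rt.nodes:
            assert rt.parent[node] is node.parent

    def test_restriction_matches_quadratic_oracle(self):
        for seed in range(60):
            idx, m = random_instance(seed, max_leaves=80, max_hits=15)
            rt = tq.build_restriction(idx, m)
            hits = list(set(m.hits))
            expected = set(hits)
            for i in range(len(hits)):
                for j in range(i + 1, len(hits)):
                    expected.add(walk_lca(hits[i], hits[j]))
            assert set(rt.nodes) == expected
            assert len(rt.nodes) <= 2 * len(hits) - 1
            # parent links: nearest proper ancestor within the node set
            for node in rt.nodes:
                p = rt.parent[node]
                if p is None:
                    assert node is rt.root
                    continue
                assert walk_is_proper_ancestor(p, node)
                for other in rt.nodes:
                    if other not in (node, p) and \
                            walk_is_proper_ancestor(other, node):
                        assert walk_is_proper_ancestor(other, p) or other is p
            # m_count: hits below each relevant node
            for node in rt.nodes:
                truth = sum(1 for h in hits
                            if node.m <= h.post <= node.post)
                assert rt.m_count[node] == truth
            assert rt.m_count[rt.root] == len(hits)

    def test_requires_preprocessed_index(self):
        idx = tq.parse_taxonomy("((a,b)x,c)r;")
        m = tq.HitSet("r", (idx.leaf_lookup["a"], idx.leaf_lookup["b"]))
        with pytest.raises(ValueError, match="preprocess"):
            tq.build_restriction(idx, m)


class TestOracleEquivalence:
    def test_fast_naive_and_brute_force_agree(self):
        """Minimum penalty identical across all three routes, exactly."""
        for seed in range(80):
            idx, m = random_instance(seed, max_leaves=120, max_hits=20)
            for q in Q_GRID:
                oracle_best, oracle_set = brute_force_best(idx, m.hits, q)
                fast = tq.assign_fast(idx, m, q)
                naive = tq.assign_naive(idx, m, q)
                assert fast.score == oracle_best
                assert naive.score == oracle_best
                # naive enumerates every minimizer of T_i (Step 3c)
                assert set(naive.best_nodes) == oracle_set
                # every fast minimizer is a true minimizer (relevant subset)
                assert set(fast.best_nodes) <= oracle_set

    def test_f_measure_equivalence_at_half(self):
        """q=0.5 minimizers coincide with brute-force F-measure maximizers."""
        for seed in range(60):
            idx, m = random_instance(seed, max_leaves=100, max_hits=15)
            naive = tq.assign_naive(idx, m, 0.5)
            assert set(naive.best_nodes) == brute_force_f_argmax(idx, m.hits)


class TestAssignRead:
    def test_no_hits_gives_unassigned(self, fig1_index):
        a = tq.assign_read(fig1_index, tq.HitSet("r", ()), 0.5)
        assert not a.assigned and a.score == math.inf and a.n_ties == 0

    def test_single_hit_gives_leaf(self, fig1_index):
        leaf = fig1_index.leaf_lookup["s3"]
        a = tq.assign_read(fig1_index, tq.HitSet("r", (leaf,)), 0.5)
        assert a.canonical_node is leaf and a.score == 0
        assert a.counts == tq.ConfusionCounts(tp=1, fp=0, tn=0, fn=0)

    def test_ambiguous_dispatches_to_fast(self, fig1_index, fig1_hitset):
        a = tq.assign_read(fig1_index, fig1_hitset, 0.5)
        b = tq.assign_fast(fig1_index, fig1_hitset, 0.5)
        assert a.canonical_node is b.canonical_node and a.score == b.score


class TestSweepAndRanks:
    def test_sweep_grid_boundaries(self, fig1_index, fig1_hitset):
        sweep = tq.sweep_q(fig1_index, [fig1_hitset], [0.0, 0.5, 1.0])
        by_q = {a.q: a for a in sweep}
        assert by_q[0.0].score == 0 and by_q[0.0].canonical_node in fig1_hitset.hits
        assert by_q[1.0].score == 0 and by_q[1.0].canonical_node is fig1_index.root
        assert len(sweep) == 3

    def test_two_genera_of_one_family_go_to_family_at_q1(self):
        idx = tq.preprocess(tq.parse_taxonomy(
            "(((a,b)g1,(c,d)g2)f1,((e,f)g3,(g,h)g4)f2)root;"))
        hitsets = [tq.HitSet("r1", (idx.leaf_lookup["a"], idx.leaf_lookup["c"])),
                   tq.HitSet("r2", (idx.leaf_lookup["e"], idx.leaf_lookup["g"]))]
        sweep = tq.sweep_q(idx, hitsets, [1.0])
        counts, unassigned = tq.rank_distribution(sweep)
        assert counts.loc["level-1", 1.0] == 2  # both at their family node
        assert unassigned[1.0] == 0

    def test_rank_counts_conserve_assigned_reads(self, synthetic_datasets):
        cfg, idx, seqs, reads, truth, hitsets = synthetic_datasets[0]
        sweep = tq.sweep_q(idx, hitsets[:300], [0.0, 0.5, 1.0])
        counts, unassigned = tq.rank_distribution(sweep)
        n_assigned = sum(1 for h in hitsets[:300] if len(h) >= 1)
        for q in (0.0, 0.5, 1.0):
            assert counts[q].sum() == n_assigned
            assert counts[q].sum() + unassigned[q] == 300

    def test_unambiguous_reads_all_at_species(self, synthetic_datasets):
        cfg, idx, seqs, reads, truth, hitsets = synthetic_datasets[0]
        single = [h for h in hitsets if len(h) == 1][:50]
        sweep = tq.sweep_q(idx, single, [0.3])
        counts, _ = tq.rank_distribution(sweep)
        assert counts.loc["species", 0.3] == len(single)
        assert counts[0.3].sum() == len(single)
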