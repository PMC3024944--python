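"""Synthetic ranked taxonomies, reference sequences and error-bearing reads.

End-to-end testing of taxonomic assignment needs three coupled objects: a
multifurcating ranked taxonomy, leaf sequences whose similarity decays
with tree distance (this is what makes short reads ambiguous among nearby
leaves), and short reads sampled from known source leaves with
sequencing-like errors.  This module generates all three reproducibly
from a single seed, emulating a 454-style 16S rRNA amplicon experiment at
desk scale: substitution errors per base plus one-base insertions or
deletions in homopolymer runs, with reads shorter than 75% of the
expected length discarded.

Sequences evolve down the tree by independent per-site substitutions at
``per_level_substitution_rate`` per branch, so two leaves at tree distance
t differ at roughly ``1 - exp(-t * rate)`` of their sites.  The default
0.015/site/level leaves sibling species ~97% identical, matching the
conventional 16S species-level identity threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .taxonomy import TaxNode, TaxonomyIndex, parse_taxonomy, preprocess

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_RANK_PREFIX = {"domain": "d", "phylum": "p", "class": "c", "order": "o",
                "family": "f", "genus": "g"}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset.

    Rates are probabilities in [0, 1]; ``read_length`` must be shorter
    than ``seq_length``.  ``homopolymer_indel_rate`` is per homopolymer
    run (length >= 2), giving at most one +-1 bp event per run.
    """

    seed: int = 17
    n_leaves: int = 200
    ranks: int = 7
    branching: float = 3.0
    seq_length: int = 1500
    per_level_substitution_rate: float = 0.015
    read_length: int = 100
    n_reads: int = 2000
    substitution_error_rate: float = 0.005
    homopolymer_indel_rate: float = 0.01
    min_length_fraction: float = 0.75

    def __post_init__(self):
        for name in ("per_level_substitution_rate", "substitution_error_rate",
                     "homopolymer_indel_rate", "min_length_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length >= self.seq_length:
            raise ValueError("read_length must be < seq_length")
        if self.n_leaves < 1 or self.ranks < 1:
            raise ValueError("n_leaves and ranks must be positive")


def _rank_labels(ranks: int) -> List[str]:
    from .taxonomy import CANONICAL_RANKS

    if ranks == 7:
        return list(CANONICAL_RANKS)
    return [f"level{i}" for i in range(1, ranks + 1)]


def _level_widths(n_leaves: int, ranks: int, branching: float) -> List[int]:
    """Number of nodes per depth (1..ranks), bottom-heavy.

    Curated 16S taxonomies are narrow at the top (a handful of phyla) and
    wide at the bottom (several species per genus), so widths shrink
    geometrically by ``branching`` going up from the leaves, with the
    leaf level holding all ``n_leaves`` species.
    """
    widths = [n_leaves]
    w = n_leaves
    for _ in range(ranks - 1):
        w = max(1, round(w / branching))
        widths.append(w)
    widths.reverse()
    return widths


def _random_composition(rng: np.random.Generator, total: int, parts: int) -> List[int]:
    """``total`` split into ``parts`` positive integers, uniformly at random."""
    if parts == 1:
        return [total]
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    return np.diff(np.concatenate(([0], cuts, [total]))).astype(int).tolist()


def _lineage_rows(rng: np.random.Generator, n_leaves: int, ranks: int,
                  branching: float) -> List[List[str]]:
    """Top-down layered construction: level d's nodes are partitioned among
    level d-1's nodes (every parent gets >= 1 child), so every leaf ends
    at depth ``ranks``.  Internal names are unique per rank (prefix +
    counter).
    """
    labels = _rank_labels(ranks)
    widths = _level_widths(n_leaves, ranks, branching)
    rows: List[List[str]] = []

    # paths[i] is the lineage (list of names) of the i-th node at the
    # current level, in left-to-right order
    paths: List[List[str]] = [[]]
    for depth in range(1, ranks + 1):
        width = max(widths[depth - 1], len(paths))
        parts = _random_composition(rng, width, len(paths))
        prefix = _RANK_PREFIX.get(labels[depth - 1], f"L{depth}n")
        new_paths: List[List[str]] = []
        counter = 0
        for parent_path, n_children in zip(paths, parts):
            for _ in range(n_children):
                counter += 1
                if depth == ranks:
                    name = f"s{counter:04d}"
                else:
                    name = f"{prefix}{counter:03d}"
                new_paths.append(parent_path + [name])
        paths = new_paths
    for path in paths:
        rows.append([path[-1]] + path)
    return rows


def random_taxonomy(seed: int, n_leaves: int, ranks: int = 7,
                    branching: float = 3.0) -> TaxonomyIndex:
    """A random uniform-depth ranked taxonomy (no sequences), preprocessed."""
    rng = np.random.default_rng([int(seed), 0])
    rows = _lineage_rows(rng, n_leaves, ranks, branching)
    header = ["leaf"] + _rank_labels(ranks)
    text = "\n".join(["\t".join(header)] + ["\t".join(r) for r in rows]) + "\n"
    return preprocess(parse_taxonomy(text, format="lineage_table"))


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(len(seq)) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def simulate_taxonomy(cfg: SimConfig) -> Tuple[TaxonomyIndex, Dict[str, str]]:
    """Generate the ranked taxonomy and its leaf reference sequences.

    The root sequence is uniform random; each child's sequence is its
    parent's with independent per-site substitutions at
    ``per_level_substitution_rate``.  Returns the preprocessed index and a
    ``leaf id -> sequence`` dict.
    """
    idx = random_taxonomy(cfg.seed, cfg.n_leaves, cfg.ranks, cfg.branching)
    rng = np.random.default_rng([int(cfg.seed), 1])
    root_seq = rng.integers(0, 4, size=cfg.seq_length, dtype=np.int64)
    seqs: Dict[str, str] = {}
    stack: List[Tuple[TaxNode, np.ndarray]] = [(idx.root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.is_leaf:
            seqs[node.id] = _ALPHABET[seq].tobytes().decode("ascii")
            continue
        # reversed so that left-to-right children are processed in order
        for child in reversed(node.children):
            stack.append((child, _mutate(seq, cfg.per_level_substitution_rate, rng)))
    return idx, seqs


def _homopolymer_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """At most one +-1 bp event per homopolymer run of length >= 2."""
    if rate == 0.0:
        return seq
    out: List[str] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if j - i >= 2 and rng.random() < rate:
            if rng.random() < 0.5:
                run = run[:-1]
            else:
                run = run + run[0]
        out.append(run)
        i = j
    return "".join(out)


def simulate_reads(cfg: SimConfig, idx: TaxonomyIndex, seqs: Dict[str, str],
                   window: Optional[Tuple[int, int]] = None
                   ) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Sample error-bearing reads with known true source leaves.

    Each read takes a uniform source leaf and a uniform ``read_length``
    window (optionally restricted to ``window``, 0-based half-open), then
    per-base substitution errors and homopolymer indels are applied.
    Reads shorter than ``min_length_fraction * read_length`` after indels
    are discarded.  Returns ``(reads, truth)`` where reads are
    ``(read_id, sequence)`` pairs and truth is a DataFrame with columns
    read_id, true_hit, source_start, source_end.
    """
    rng = np.random.default_rng([int(cfg.seed), 2])
    leaf_ids = sorted(seqs)
    min_len = cfg.min_length_fraction * cfg.read_length
    reads: List[Tuple[str, str]] = []
    truth_rows = []
    for i in range(cfg.n_reads):
        leaf = leaf_ids[int(rng.integers(0, len(leaf_ids)))]
        seq = seqs[leaf]
        ws, we = (0, len(seq)) if window is None else window
        if not (0 <= ws < we <= len(seq)):
            raise ValueError(f"window {ws, we} outside sequence of length {len(seq)}")
        if we - ws < cfg.read_length:
            raise ValueError("window shorter than read_length")
        start = int(rng.integers(ws, we - cfg.read_length + 1))
        raw = seq[start:start + cfg.read_length]
        arr = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
        codes = np.searchsorted(_ALPHABET, arr)  # ACGT sorted, so this inverts
        codes = _mutate(codes, cfg.substitution_error_rate, rng)
        read_seq = _homopolymer_indels(_ALPHABET[codes].tobytes().decode("ascii"),
                                       cfg.homopolymer_indel_rate, rng)
        if len(read_seq) < min_len:
            continue
        read_id = f"r{i:05d}"
        reads.append((read_id, read_seq))
        truth_rows.append({"read_id": read_id, "true_hit": leaf,
                           "source_start": start,
                           "source_end": start + cfg.read_length})
    truth = pd.DataFrame(truth_rows,
                         columns=["read_id", "true_hit", "source_start", "source_end"])
    return reads, truth


def simulate_region_reads(cfg: SimConfig, idx: TaxonomyIndex, seqs: Dict[str, str],
                          window: Tuple[int, int]
                          ) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Reads restricted to a subregion of each reference (e.g. a
    hypervariable region): source windows are drawn from ``[start, end)``
    of every leaf sequence.
    """
    return simulate_reads(cfg, idx, seqs, window=window)


def simulate_dataset(cfg: SimConfig, k: int = 2,
                     window: Optional[Tuple[int, int]] = None):
    """Convenience pipeline: taxonomy + references + reads + hit sets.

    Matches the reads against the references with the built-in k-mismatch
    matcher and attaches the true source leaf to every hit set.  Returns
    ``(idx, seqs, reads, truth, hitsets)``.
    """
    from .hits import match_k_mismatch

    idx, seqs = simulate_taxonomy(cfg)
    reads, truth = simulate_reads(cfg, idx, seqs, window=window)
    refs = [(leaf, seqs[leaf]) for leaf in sorted(seqs)]
    truth_map = dict(zip(truth["read_id"], truth["true_hit"]))
    hitsets = match_k_mismatch(reads, refs, idx, k=k, truth=truth_map)
    return idx, seqs, reads, truth, hitsets
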