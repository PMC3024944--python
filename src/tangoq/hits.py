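"""Per-read hit sets: the candidate leaves a read matches.

A read's hit set ``M_i`` is the set of taxonomy leaves whose reference
sequence contains a window within ``k`` mismatches (Hamming distance) of
the read.  Hit sets normally come from an external mapper; this module
reads them from a simple TSV, groups BLAST tabular output into e-value
ties, or computes them directly with the built-in matcher (a small
stand-in for a production read mapper, adequate for simulated data and
demos).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .taxonomy import TaxNode, TaxonomyIndex

logger = logging.getLogger(__name__)

BLAST_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


@dataclass(frozen=True)
class HitSet:
    """The matched leaves of one read (``M_i``), plus the true source leaf
    ``H_i`` when known (simulated data only).

    Reads with an empty hit set are retained and later reported as
    unassigned.
    """

    read_id: str
    hits: Tuple[TaxNode, ...]
    true_hit: Optional[TaxNode] = None

    def __post_init__(self):
        if len(set(self.hits)) != len(self.hits):
            raise ValueError(f"duplicate hits in HitSet for read {self.read_id!r}")

    def __len__(self) -> int:
        return len(self.hits)

    @property
    def is_ambiguous(self) -> bool:
        return len(self.hits) >= 2


def _resolve(idx: TaxonomyIndex, name: str, where: str) -> TaxNode:
    node = idx.leaf_lookup.get(name)
    if node is None:
        raise ValueError(f"unknown leaf name {name!r} in {where}")
    return node


def read_hits_tsv(source, idx: TaxonomyIndex) -> List[HitSet]:
    """Read hit sets from TSV rows ``read_id <TAB> leaf,leaf,...`` with an
    optional third ``true_hit`` column.  Duplicate leaves within a row are
    deduplicated with a warning; unknown leaf names are hard errors.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    out: List[HitSet] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) not in (2, 3):
            raise ValueError(f"malformed hits row {lineno}: {line!r}")
        read_id, hit_field = parts[0], parts[1]
        names = [n for n in hit_field.split(",") if n] if hit_field else []
        seen: Dict[str, None] = {}
        for n in names:
            if n in seen:
                logger.warning("read %s row %d: duplicate hit %r deduplicated",
                               read_id, lineno, n)
            seen[n] = None
        hits = tuple(_resolve(idx, n, f"row {lineno}") for n in seen)
        true_hit = None
        if len(parts) == 3 and parts[2]:
            true_hit = _resolve(idx, parts[2], f"row {lineno} (true_hit)")
        out.append(HitSet(read_id=read_id, hits=hits, true_hit=true_hit))
    return out


def read_blast_ties(source, idx: TaxonomyIndex, evalue_cutoff: float = 1e-3) -> List[HitSet]:
    """Group BLAST tabular (outfmt 6) lines into per-read e-value ties.

    For each query, keeps every subject whose e-value equals the query's
    minimum e-value, provided that minimum is <= ``evalue_cutoff``; queries
    whose best e-value exceeds the cutoff get an empty hit set.
    """
    df = pd.read_csv(source, sep="\t", header=None, names=BLAST_COLUMNS, dtype=str)
    try:
        evalues = df["evalue"].astype(float)
    except ValueError as exc:
        raise ValueError(f"unparseable e-value in BLAST table: {exc}") from exc
    df = df.assign(_e=evalues)
    out: List[HitSet] = []
    for qid in df["qseqid"].drop_duplicates():
        sub = df[df["qseqid"] == qid]
        best = sub["_e"].min()
        if best <= evalue_cutoff:
            names = list(dict.fromkeys(sub.loc[sub["_e"] == best, "sseqid"]))
        else:
            names = []
        hits = tuple(_resolve(idx, n, f"BLAST query {qid!r}") for n in names)
        out.append(HitSet(read_id=str(qid), hits=hits))
    return out


# --- built-in k-mismatch matcher ------------------------------------------
#
# Criterion: leaf is a hit iff some reference window of length |read| has
# Hamming distance <= k to the read (N mismatches everything).  The search
# uses the pigeonhole principle: split the read into k+1 blocks; any window
# within k mismatches matches at least one block exactly, so exact-seed
# lookup followed by windowed Hamming verification finds all hits.


def _parse_fasta(source) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(source, "fasta")]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str, n_code: int) -> np.ndarray:
    """ASCII bytes with 'N' remapped so that read-N vs ref-N still mismatches."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    arr[arr == ord("N")] = n_code
    return arr


class _SeedIndex:
    """Exact-substring index over the reference sequences, per seed length."""

    def __init__(self, refs: Sequence[Tuple[str, str]]):
        self.refs = refs
        self.ref_arrays = [_encode(seq, n_code=1) for _, seq in refs]
        self._by_len: Dict[int, Dict[str, List[Tuple[int, int]]]] = {}

    def table(self, blen: int) -> Dict[str, List[Tuple[int, int]]]:
        tab = self._by_len.get(blen)
        if tab is None:
            tab = {}
            for ri, (_, seq) in enumerate(self.refs):
                for pos in range(len(seq) - blen + 1):
                    tab.setdefault(seq[pos:pos + blen], []).append((ri, pos))
            self._by_len[blen] = tab
        return tab


def _match_one(read: str, index: _SeedIndex, k: int) -> set:
    """Reference indices with some window at Hamming distance <= k."""
    L = len(read)
    if L <= k:
        # every window is trivially within k mismatches
        return {ri for ri, arr in enumerate(index.ref_arrays) if len(arr) >= L}
    read_arr = _encode(read, n_code=2)
    bounds = [round(i * L / (k + 1)) for i in range(k + 2)]
    matched: set = set()
    candidates: Dict[int, set] = {}
    for b in range(k + 1):
        start, end = bounds[b], bounds[b + 1]
        if end - start == 0:
            continue
        block = read[start:end]
        if "N" in block:
            continue  # a block with N can never be the exact-match block
        for ri, pos in index.table(end - start).get(block, ()):
            ws = pos - start
            if ws < 0 or ws + L > len(index.ref_arrays[ri]):
                continue
            candidates.setdefault(ri, set()).add(ws)
    for ri, starts in candidates.items():
        arr = index.ref_arrays[ri]
        for ws in starts:
            if int(np.count_nonzero(arr[ws:ws + L] != read_arr)) <= k:
                matched.add(ri)
                break
    return matched


def match_k_mismatch(reads, refs, idx: TaxonomyIndex, k: int = 2,
                     revcomp: bool = False,
                     truth: Optional[Dict[str, str]] = None) -> List[HitSet]:
    """Compute hit sets by scanning reference windows at Hamming distance <= k.

    Parameters
    ----------
    reads, refs : FASTA paths/handles, or pre-parsed ``[(id, seq), ...]`` lists.
    idx : taxonomy whose leaf ids are the reference ids.
    k : maximum number of mismatches (default 2).
    revcomp : also scan the reverse complement of each read.
    truth : optional mapping read id -> true source leaf id, recorded as
        ``true_hit`` on the returned hit sets.

    A leaf matched through several windows counts once.  Empty reads are
    skipped with a warning.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    read_recs = reads if isinstance(reads, list) else _parse_fasta(reads)
    ref_recs = refs if isinstance(refs, list) else _parse_fasta(refs)
    for ref_id, _ in ref_recs:
        _resolve(idx, ref_id, "reference FASTA")
    index = _SeedIndex(ref_recs)
    out: List[HitSet] = []
    for read_id, seq in read_recs:
        seq = seq.upper()
        if not seq:
            logger.warning("read %s is empty; skipped", read_id)
            continue
        matched = _match_one(seq, index, k)
        if revcomp:
            matched |= _match_one(reverse_complement(seq), index, k)
        hits = tuple(idx.leaf_lookup[ref_recs[ri][0]]
                     for ri in sorted(matched))
        true_node = None
        if truth is not None and read_id in truth:
            true_node = _resolve(idx, truth[read_id], f"truth for read {read_id!r}")
        out.append(HitSet(read_id=read_id, hits=hits, true_hit=true_node))
    return out


def hitsets_to_tsv(hitsets: Sequence[HitSet]) -> str:
    """Serialize hit sets to the TSV format accepted by :func:`read_hits_tsv`."""
    lines = []
    for hs in hitsets:
        row = [hs.read_id, ",".join(h.id for h in hs.hits)]
        if hs.true_hit is not None:
            row.append(hs.true_hit.id)
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
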