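"""Reverse-read processing: quality trimming, rRNA removal, mapping, counting.

The reverse read of each pair carries the transcript fragment.  It is
quality-trimmed from the 3' end with the BWA ``-q`` rule, screened against
ribosomal sequences with a k-mer filter, mapped to the transcriptome by
seed-and-extend over a k-mer index, and finally resolved to a gene using an
annotation restricted to polyadenylated transcripts.  Every read receives
exactly one status, so status counters partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "STATUSES",
    "TrimmedRead",
    "GeneAssignment",
    "trim_bwa",
    "RrnaIndex",
    "TranscriptomeIndex",
    "map_read",
    "assign_gene",
    "reverse_complement",
]

#: Mutually exclusive per-read outcomes, in pipeline order.
STATUSES = ("too_short", "ribosomal", "unmapped", "ambiguous", "not_polyA", "assigned")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TrimmedRead:
    read_id: Optional[str]
    seq: str
    quals: tuple[int, ...]
    kept: bool
    trimmed_bases: int


def trim_bwa(
    seq: str,
    quals: Sequence[int] | np.ndarray,
    q_threshold: int = 20,
    min_length: int = 25,
    read_id: Optional[str] = None,
) -> TrimmedRead:
    """3' quality trimming with the BWA ``-q`` rule.

    Scanning from the 3' end, the running sum of ``(q_threshold - q_i)`` is
    computed for every cut point c (retain the prefix ``[0, c)``); the read is
    cut at the c maximizing that sum, ties resolved toward the longest
    retained prefix.  If the maximum is <= 0 the read is untouched.  Reads
    shorter than ``min_length`` after trimming are flagged ``kept=False``.
    """
    q = np.asarray(quals, dtype=np.int64)
    if len(seq) != q.size:
        raise ValueError(f"sequence length {len(seq)} != quality length {q.size}")
    if q.size == 0:
        return TrimmedRead(read_id, "", (), min_length <= 0, 0)
    # s[c] = sum_{i=c}^{L-1} (q_threshold - q_i)
    s = np.cumsum((q_threshold - q)[::-1])[::-1]
    best = int(s.max())
    if best <= 0:
        cut = q.size
    else:
        # largest c attaining the max keeps the most bases
        cut = q.size - 1 - int(np.argmax(s[::-1]))
    trimmed = q.size - cut
    return TrimmedRead(
        read_id, seq[:cut], tuple(int(x) for x in q[:cut]), cut >= min_length, trimmed
    )


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class RrnaIndex:
    """k-mer screen for ribosomal reads.

    A read is flagged ribosomal when it shares at least ``min_shared``
    distinct k-mers with any single rRNA sequence; both the rRNA's strands
    are indexed so reverse-complement reads are caught.
    """

    def __init__(self, rrna_seqs: Sequence[tuple[str, str]], k: int = 15):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self._sets: list[set[str]] = []
        self.ids: list[str] = []
        for rid, seq in rrna_seqs:
            seq = seq.upper()
            self._sets.append(_kmers(seq, k) | _kmers(reverse_complement(seq), k))
            self.ids.append(rid)
        self._union: set[str] = set().union(*self._sets) if self._sets else set()

    def shared_kmers(self, seq: str) -> int:
        """Max number of distinct k-mers shared with any one rRNA sequence."""
        read_kmers = _kmers(seq.upper(), self.k)
        if not read_kmers & self._union:
            return 0
        return max(len(read_kmers & s) for s in self._sets)

    def is_ribosomal(self, seq: str, min_shared: int = 2) -> bool:
        if self.k > len(seq):
            return False
        return self.shared_kmers(seq) >= min_shared


class TranscriptomeIndex:
    """Exact k-mer index over transcript sequences for seed-and-extend mapping."""

    def __init__(self, sequences: dict[str, str], k: int = 15):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.gene_ids = list(sequences)
        self.seqs = [sequences[g].upper() for g in self.gene_ids]
        index: dict[str, list[tuple[int, int]]] = {}
        for gi, seq in enumerate(self.seqs):
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append((gi, pos))
        self._index = index

    def seed_hits(self, seq: str, stride: int) -> dict[int, dict[int, int]]:
        """gene index -> {diagonal: seed count} from stride-sampled read k-mers."""
        k = self.k
        n = len(seq) - k + 1
        if n <= 0:
            return {}
        positions = list(range(0, n, max(1, stride)))
        if positions[-1] != n - 1:
            positions.append(n - 1)  # always seed the 3' terminal k-mer
        hits: dict[int, dict[int, int]] = {}
        index = self._index
        for rpos in positions:
            for gi, tpos in index.get(seq[rpos : rpos + k], ()):
                diag = hits.setdefault(gi, {})
                d = tpos - rpos
                diag[d] = diag.get(d, 0) + 1
        return hits

    def extend_score(self, seq: str, gene_index: int, diag: int) -> int:
        """Ungapped match count of the read against a transcript at one offset."""
        t = self.seqs[gene_index]
        start_t = max(diag, 0)
        start_r = start_t - diag
        end_t = min(len(t), diag + len(seq))
        n = end_t - start_t
        if n <= 0:
            return 0
        r_seg = seq[start_r : start_r + n]
        t_seg = t[start_t:end_t]
        if r_seg == t_seg:
            return n
        a = np.frombuffer(r_seg.encode(), dtype=np.uint8)
        b = np.frombuffer(t_seg.encode(), dtype=np.uint8)
        return int((a == b).sum())


def map_read(
    seq: str,
    index: TranscriptomeIndex,
    min_seeds: int = 2,
    stride: int = 5,
    check_reverse: bool = True,
) -> list[tuple[str, int]]:
    """Map a read to candidate genes by k-mer seed-and-extend.

    Genes sharing at least ``min_seeds`` sampled seed k-mers (either strand)
    are scored by the ungapped match count on their best diagonal; candidates
    are returned sorted by descending score (ties kept, ordered by gene id).
    An empty list means unmapped.
    """
    seq = seq.upper()
    queries = [seq]
    if check_reverse:
        queries.append(reverse_complement(seq))
    best: dict[int, int] = {}
    for q in queries:
        for gi, diags in index.seed_hits(q, stride).items():
            if sum(diags.values()) < min_seeds:
                continue
            diag = max(diags, key=lambda d: (diags[d], -abs(d)))
            score = index.extend_score(q, gi, diag)
            if score > best.get(gi, -1):
                best[gi] = score
    out = [(index.gene_ids[gi], sc) for gi, sc in best.items()]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


@dataclass(frozen=True)
class GeneAssignment:
    read_id: Optional[str]
    gene_id: Optional[str]
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.gene_id is None) == (self.status == "assigned"):
            raise ValueError("gene_id must be set iff status == 'assigned'")


def assign_gene(
    candidates: Sequence[tuple[str, int]],
    annotation: dict[str, bool],
    read_id: Optional[str] = None,
) -> GeneAssignment:
    """Resolve mapper candidates to one gene under the poly-A-only annotation.

    No candidates -> unmapped.  A tie at the top score -> ambiguous (the read
    is discarded, mirroring union-mode multi-hit handling).  A unique top hit
    is assigned unless its gene is not flagged polyadenylated (-> not_polyA).
    """
    if not candidates:
        return GeneAssignment(read_id, None, "unmapped")
    top_gene, top_score = candidates[0]
    if len(candidates) > 1 and candidates[1][1] == top_score:
        return GeneAssignment(read_id, None, "ambiguous")
    if top_gene not in annotation:
        raise KeyError(f"gene {top_gene!r} missing from annotation (index mismatch)")
    if not annotation[top_gene]:
        return GeneAssignment(read_id, None, "not_polyA")
    return GeneAssignment(read_id, top_gene, "assigned")
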