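"""K-mer seeded pairwise similarity search and the allele-candidate test.

The workflow needs every pair of unigenes that could be alleles of the same
locus.  This module finds them in two stages, the way seeded aligners do:

1. *seeding* — overlapping k-mers of all sequences are indexed; pairs that
   share enough k-mers on a consistent diagonal (on either strand) become
   candidates, with an estimated offset between the two sequences;
2. *alignment* — each candidate is aligned with a banded overlap alignment
   around that offset (match +1, mismatch -2, gap -3; identity counted over
   all aligned columns, gaps included).

A candidate pair is accepted as putative alleles only when the alignment
reaches the identity and length thresholds *and* spans essentially the full
mutual overlap of the two sequences — paralogs tend to align well in
conserved stretches but not throughout their overlap.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from . import _dp
from .io import SequenceRecord

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0 C=1 G=2 T=3, everything else=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class KmerIndex:
    """Postings of every N-free k-mer of every indexed sequence."""

    k: int
    postings: dict[int, list[tuple[str, int]]]
    indexed_ids: set[str]


@dataclass
class AlignmentResult:
    """A scored pairwise alignment between two sequences.

    Coordinates are 0-based half-open.  For strand ``-`` the subject
    coordinates refer to the reverse-complemented subject.  ``cigar`` is a
    list of ``(op, length)`` run-length tuples with ops in {"=", "X", "D",
    "I"} ("D" consumes the query, "I" the subject).
    """

    query_id: str
    subject_id: str
    q_len: int
    s_len: int
    strand: str
    identity: float
    aligned_len: int
    matches: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    cigar: list[tuple[str, int]] = field(default_factory=list)
    score: int = 0

    @property
    def offset(self) -> int:
        """Diagonal offset: query position p aligns near subject p - offset."""
        return self.q_start - self.s_start

    def columns(self):
        """Yield (q_pos, s_pos, op) per alignment column; gap side is None."""
        qi, si = self.q_start, self.s_start
        for op, length in self.cigar:
            for _ in range(length):
                if op in ("=", "X"):
                    yield qi, si, op
                    qi += 1
                    si += 1
                elif op == "D":
                    yield qi, None, op
                    qi += 1
                else:
                    yield None, si, op
                    si += 1


def _kmers(codes: np.ndarray, k: int):
    """Yield (pos, kmer_int) for every N-free k-mer, via rolling hash."""
    n = codes.size
    if n < k:
        return
    mask = (1 << (2 * k)) - 1
    value = 0
    valid = 0  # length of current N-free run ending at i
    for i in range(n):
        c = int(codes[i])
        if c > 3:
            valid = 0
            value = 0
            continue
        value = ((value << 2) | c) & mask
        valid += 1
        if valid >= k:
            yield i - k + 1, value


def build_index(records: list[SequenceRecord], k: int = 12) -> KmerIndex:
    """Index all overlapping k-mers of all records (k-mers with N skipped)."""
    if not 8 <= k <= 16:
        raise ValueError(f"k must be in [8, 16], got {k}")
    postings: dict[int, list[tuple[str, int]]] = defaultdict(list)
    for rec in records:
        codes = encode(rec.residues)
        for pos, kmer in _kmers(codes, k):
            postings[kmer].append((rec.seq_id, pos))
    return KmerIndex(k=k, postings=dict(postings), indexed_ids={r.seq_id for r in records})


@dataclass(frozen=True)
class CandidatePair:
    query_id: str
    subject_id: str
    strand: str
    offset: int
    support: int


def find_candidate_pairs(
    index: KmerIndex,
    records: list[SequenceRecord],
    min_shared_kmers: int = 3,
    band: int = 15,
    stride: int = 1,
) -> list[CandidatePair]:
    """Pairs sharing enough k-mers on one diagonal, on either strand.

    Each unordered pair is reported once, with the modal diagonal offset
    (support counted within ``band`` of the mode).  ``stride`` subsamples the
    query-side k-mer scan; any pair with a >=300 bp exact shared stretch
    still yields far more than ``min_shared_kmers`` sampled hits for strides
    up to ~30.
    """
    if min_shared_kmers < 1:
        raise ValueError("min_shared_kmers must be >= 1")
    order = {rec.seq_id: i for i, rec in enumerate(records)}
    lengths = {rec.seq_id: len(rec) for rec in records}
    k = index.k
    results: dict[tuple[str, str], CandidatePair] = {}
    for rec in records:
        qi = order[rec.seq_id]
        q_len = lengths[rec.seq_id]
        # diag counters per (subject, strand)
        diags: dict[tuple[str, str], dict[int, int]] = defaultdict(lambda: defaultdict(int))
        for strand, seq in (("+", rec.residues), ("-", revcomp(rec.residues))):
            codes = encode(seq)
            for pos, kmer in _kmers(codes, k):
                if stride > 1 and pos % stride:
                    continue
                for sid, spos in index.postings.get(kmer, ()):
                    if order.get(sid, -1) <= qi:
                        continue
                    diags[(sid, strand)][pos - spos] += 1
        for (sid, strand), counter in diags.items():
            modal = min(
                (d for d in counter), key=lambda d: (-counter[d], d)
            )
            support = sum(
                c for d, c in counter.items() if abs(d - modal) <= band
            )
            if support < min_shared_kmers:
                continue
            if strand == "-":
                # counts were on (revcomp(query), subject); convert the
                # diagonal to (query, revcomp(subject)) geometry
                offset = q_len - lengths[sid] - modal
            else:
                offset = modal
            key = (rec.seq_id, sid)
            prev = results.get(key)
            if prev is None or support > prev.support:
                results[key] = CandidatePair(rec.seq_id, sid, strand, offset, support)
    return sorted(results.values(), key=lambda c: (c.query_id, c.subject_id))


def _cigar_from_ops(ops: np.ndarray) -> list[tuple[str, int]]:
    symbols = "=XDI"
    cigar: list[tuple[str, int]] = []
    for op in ops:
        sym = symbols[op]
        if cigar and cigar[-1][0] == sym:
            cigar[-1] = (sym, cigar[-1][1] + 1)
        else:
            cigar.append((sym, 1))
    return cigar


def banded_align(
    a: SequenceRecord,
    b: SequenceRecord,
    offset: int,
    band: int = 15,
    strand: str = "+",
) -> AlignmentResult:
    """Overlap alignment of ``a`` vs ``b`` around a diagonal offset.

    ``offset`` means: position ``p`` of ``a`` corresponds to position
    ``p - offset`` of the (oriented) ``b``.  The alignment is global from
    the start of the implied overlap and free at the far end, confined to
    ``band`` diagonals either side of the offset.
    """
    if band < 1:
        raise ValueError("band must be >= 1")
    b_seq = b.residues if strand == "+" else revcomp(b.residues)
    qs = max(0, offset)
    ss = max(0, -offset)
    if qs >= len(a.residues) or ss >= len(b_seq):
        raise ValueError(f"offset {offset} implies no overlap ({a.seq_id} vs {b.seq_id})")
    qa = encode(a.residues[qs:])
    sb = encode(b_seq[ss:])
    score, end_i, end_j, ops = _dp.banded_overlap_align(qa, sb, band)
    ops = np.asarray(ops)
    matches = int((ops == _dp.OP_MATCH).sum())
    aligned_len = int(ops.size)
    identity = matches / aligned_len if aligned_len else 0.0
    return AlignmentResult(
        query_id=a.seq_id,
        subject_id=b.seq_id,
        q_len=len(a.residues),
        s_len=len(b.residues),
        strand=strand,
        identity=identity,
        aligned_len=aligned_len,
        matches=matches,
        q_start=qs,
        q_end=qs + end_i,
        s_start=ss,
        s_end=ss + end_j,
        cigar=_cigar_from_ops(ops),
        score=int(score),
    )


def passes_allele_criteria(
    r: AlignmentResult,
    min_identity: float = 0.95,
    min_len: int = 300,
    end_slack: int = 30,
) -> bool:
    """Accept an alignment as evidence that two sequences are alleles.

    Requires identity >= ``min_identity``, alignment length >= ``min_len``
    columns, and coverage of the full mutual overlap of the two sequences to
    within ``end_slack`` bp at each end.
    """
    if r.identity < min_identity or r.aligned_len < min_len:
        return False
    o = r.offset
    q_ov_start, q_ov_end = max(0, o), min(r.q_len, r.s_len + o)
    s_ov_start, s_ov_end = max(0, -o), min(r.s_len, r.q_len - o)
    return (
        r.q_start <= q_ov_start + end_slack
        and r.q_end >= q_ov_end - end_slack
        and r.s_start <= s_ov_start + end_slack
        and r.s_end >= s_ov_end - end_slack
    )


def hit_table(hits: list[AlignmentResult]):
    """Alignment hits as a DataFrame (1-based inclusive file coordinates)."""
    import pandas as pd

    rows = []
    for r in hits:
        if r.strand == "+":
            s_start, s_end = r.s_start + 1, r.s_end
        else:  # report on the original subject strand, reversed interval
            s_start, s_end = r.s_len - r.s_start, r.s_len - r.s_end + 1
        rows.append(
            {
                "query": r.query_id,
                "subject": r.subject_id,
                "strand": r.strand,
                "identity": round(r.identity, 4),
                "aligned_len": r.aligned_len,
                "q_start": r.q_start + 1,
                "q_end": r.q_end,
                "s_start": s_start,
                "s_end": s_end,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "query", "subject", "strand", "identity", "aligned_len",
            "q_start", "q_end", "s_start", "s_end",
        ],
    )
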