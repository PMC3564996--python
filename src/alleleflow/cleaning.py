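"""Pre-assembly read cleaning for normalized cDNA libraries.

Long-read cDNA sequencing of oligo-dT-primed libraries leaves three common
artifacts in raw reads: ligated adapter/primer sequence, poly-A (or, on the
opposite strand, 5' poly-T) tails, and whole reads that are nothing but
concatenated primer copies ("multimers").  This module removes all three:

1. adapter/primer trimming — approximate occurrences of any configured
   adapter (either strand) are located and the read is cut back to its
   longest adapter-free fragment;
2. poly-A/T tail trimming — terminal mononucleotide runs, tolerating a small
   number of single-base interruptions (oligo-dT primers are deliberately
   "broken" with anchor bases, so real tails are rarely pure);
3. multimer removal — reads whose k-mer content is dominated by adapter
   k-mers are discarded, using an empirical false-discovery cutoff: the
   adapter k-mer score of each read is compared against the score
   distribution of dinucleotide-shuffled library reads, and reads above the
   ``1 - tag_fdr`` null quantile are dropped.

Stage order is adapter -> poly tail -> multimer -> minimum-length filter.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np

from .io import SequenceRecord
from .similarity import revcomp

logger = logging.getLogger(__name__)


@dataclass
class CleaningConfig:
    """Tunable thresholds of the cleaning stages (lengths in bp)."""

    adapters: dict[str, str] = field(default_factory=dict)
    min_adapter_match: int = 10
    max_adapter_mismatch_rate: float = 0.1
    poly_min_run: int = 8
    poly_max_interruptions: int = 2
    min_keep_len: int = 50
    tag_fdr: float = 0.01
    tag_k: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.max_adapter_mismatch_rate < 0.5:
            raise ValueError("max_adapter_mismatch_rate must be in (0, 0.5)")
        if self.poly_min_run < 3:
            raise ValueError("poly_min_run must be >= 3")
        if not 0 < self.tag_fdr < 1:
            raise ValueError("tag_fdr must be in (0, 1)")


@dataclass
class CleaningReport:
    """Per-individual read and base-pair accounting of one cleaning run."""

    reads_in: dict[str, int] = field(default_factory=dict)
    reads_kept: dict[str, int] = field(default_factory=dict)
    bp_in: dict[str, int] = field(default_factory=dict)
    bp_kept: dict[str, int] = field(default_factory=dict)
    discarded_as_multimer: dict[str, int] = field(default_factory=dict)
    adapter_trims: dict[str, int] = field(default_factory=dict)
    poly_trims: dict[str, int] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        inds = sorted(self.reads_in)
        return pd.DataFrame(
            {
                "individual_id": inds,
                "reads_in": [self.reads_in[i] for i in inds],
                "reads_kept": [self.reads_kept.get(i, 0) for i in inds],
                "bp_in": [self.bp_in[i] for i in inds],
                "bp_kept": [self.bp_kept.get(i, 0) for i in inds],
                "discarded_as_multimer": [
                    self.discarded_as_multimer.get(i, 0) for i in inds
                ],
                "adapter_trims": [self.adapter_trims.get(i, 0) for i in inds],
                "poly_trims": [self.poly_trims.get(i, 0) for i in inds],
            }
        )


def _adapter_hits(seq: str, adapter: str, min_match: int, max_rate: float):
    """All (start, end) spans where ``adapter`` matches ``seq``.

    The full adapter is slid across the read, including partial overlaps at
    both read ends; a placement is a hit when the overlap is at least
    ``min_match`` bp with a mismatch fraction of at most ``max_rate``.
    """
    hits = []
    n, m = len(seq), len(adapter)
    for offset in range(-(m - min_match), n - min_match + 1):
        s_lo = max(0, offset)
        s_hi = min(n, offset + m)
        overlap = s_hi - s_lo
        if overlap < min_match:
            continue
        mism = 0
        allowed = int(max_rate * overlap)
        for i in range(s_lo, s_hi):
            if seq[i] != adapter[i - offset]:
                mism += 1
                if mism > allowed:
                    break
        if mism <= allowed:
            hits.append((s_lo, s_hi))
    return hits


def trim_adapters(record: SequenceRecord, config: CleaningConfig) -> SequenceRecord:
    """Remove adapter occurrences, keeping the longest adapter-free fragment.

    Hits are searched on both strands of every configured adapter.  Each hit
    splits the read; the longer flanking fragment survives and the search
    repeats until no hit remains.  The result may be empty (residues "");
    the caller handles discarding.
    """
    seq = record.residues
    queries = []
    for adapter in config.adapters.values():
        queries.append(adapter)
        queries.append(revcomp(adapter))
    while seq:
        found = None
        for adapter in queries:
            hits = _adapter_hits(
                seq, adapter, config.min_adapter_match, config.max_adapter_mismatch_rate
            )
            if hits:
                found = hits[0]
                break
        if found is None:
            break
        start, end = found
        left, right = seq[:start], seq[end:]
        seq = left if len(left) >= len(right) else right
    if seq == record.residues:
        return record
    if not seq:
        # empty placeholder; filtered out by clean_library
        return SequenceRecord(record.seq_id, record.individual_id, record.group,
                              "N", record.source)
    return replace(record, residues=seq)


def _qualifying_tail_span(seq: str, base: str, end: str,
                          min_run: int, max_interruptions: int) -> int:
    """Length of the maximal terminal poly-``base`` span at the given end.

    The span may contain up to ``max_interruptions`` single-base
    interruptions (each flanked by ``base``); it qualifies only if it
    contains at least ``min_run`` copies of ``base``.  Returns 0 when no
    qualifying span exists.
    """
    chars = seq if end == "5" else seq[::-1]
    n = len(chars)
    i = 0
    interruptions = 0
    run_bases = 0
    best = 0
    while i < n:
        if chars[i] == base:
            run_bases += 1
            i += 1
            if run_bases >= min_run:
                best = i
        elif (
            interruptions < max_interruptions
            and i + 1 < n
            and chars[i + 1] == base
            and i > 0  # interruption must be inside the run, not terminal
        ):
            interruptions += 1
            i += 1
        else:
            break
    return best


def trim_poly_tail(record: SequenceRecord, config: CleaningConfig) -> SequenceRecord:
    """Trim 3' poly-A and 5' poly-T tails (interruption-tolerant)."""
    seq = record.residues
    cut3 = _qualifying_tail_span(
        seq, "A", "3", config.poly_min_run, config.poly_max_interruptions
    )
    if cut3:
        seq = seq[: len(seq) - cut3]
    cut5 = _qualifying_tail_span(
        seq, "T", "5", config.poly_min_run, config.poly_max_interruptions
    )
    if cut5:
        seq = seq[cut5:]
    if seq == record.residues:
        return record
    if not seq:
        return SequenceRecord(record.seq_id, record.individual_id, record.group,
                              "N", record.source)
    return replace(record, residues=seq)


def _kmer_set(seqs, k: int) -> set[str]:
    kmers: set[str] = set()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            kmers.add(seq[i : i + k])
    return kmers


def _adapter_kmer_set(adapters: dict[str, str], k: int) -> set[str]:
    """K-mers of every adapter concatenation junction, both strands.

    Multimer reads are adapters ligated head-to-tail, so the reference set
    is built from all ordered two-adapter concatenations (which subsumes
    the k-mers of each single adapter).
    """
    seqs = []
    values = list(adapters.values())
    for a in values:
        for b in values:
            seqs.append(a + b)
            seqs.append(revcomp(a + b))
    return _kmer_set(seqs, k)


def tag_multimer_score(
    record: SequenceRecord, adapters: dict[str, str], tag_k: int = 8
) -> float:
    """Fraction of the read's overlapping k-mers found in the adapter set.

    The adapter k-mer set includes concatenation junctions on both strands,
    so a read that is nothing but repeated adapter scores 1.0.  Reads
    shorter than ``tag_k`` score 0 (with a warning).
    """
    if not adapters:
        raise ValueError("adapters must be non-empty")
    seq = record.residues
    if len(seq) < tag_k:
        logger.warning("%s shorter than tag_k=%d; multimer score 0", record.seq_id, tag_k)
        return 0.0
    ref = _adapter_kmer_set(adapters, tag_k)
    total = len(seq) - tag_k + 1
    shared = sum(1 for i in range(total) if seq[i : i + tag_k] in ref)
    return shared / total


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide composition.

    Altschul–Erickson shuffle: a uniform random Eulerian path through the
    order-1 de Bruijn multigraph of the sequence, with the same start and
    end residues as the original.
    """
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    # pick a random final edge per vertex until the final-edge graph is an
    # arborescence rooted at the end vertex (guarantees an Eulerian path)
    while True:
        finals = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        ok = True
        for v in vertices:
            seen = set()
            u = v
            while u != last and u in finals and u not in seen:
                seen.add(u)
                u = finals[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    ordered: dict[str, list[str]] = {}
    for v, lst in edges.items():
        pool = list(lst)
        if v in finals:
            pool.remove(finals[v])
        perm = rng.permutation(len(pool))
        pool = [pool[i] for i in perm]
        if v in finals:
            pool.append(finals[v])
        ordered[v] = pool
    out = [seq[0]]
    ptr: dict[str, int] = defaultdict(int)
    u = seq[0]
    while u in ordered and ptr[u] < len(ordered[u]):
        nxt = ordered[u][ptr[u]]
        ptr[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


def multimer_null_quantile(
    records: list[SequenceRecord],
    config: CleaningConfig,
    rng: np.random.Generator,
    n_null: int = 1000,
) -> float:
    """``1 - tag_fdr`` quantile of adapter k-mer scores of shuffled reads."""
    if not records:
        return 1.0
    idx = rng.integers(0, len(records), size=n_null)
    scores = np.empty(n_null)
    for j, i in enumerate(idx):
        rec = records[i]
        shuffled = dinucleotide_shuffle(rec.residues, rng)
        scores[j] = tag_multimer_score(
            replace(rec, residues=shuffled) if shuffled else rec,
            config.adapters,
            config.tag_k,
        )
    return float(np.quantile(scores, 1.0 - config.tag_fdr))


def clean_library(
    records: list[SequenceRecord],
    config: CleaningConfig,
    seed: int = 1,
    n_null: int = 1000,
) -> tuple[list[SequenceRecord], CleaningReport]:
    """Run all cleaning stages over a library of raw reads.

    Returns the kept (trimmed) reads and a per-individual report.  The
    multimer null distribution is built from ``n_null`` dinucleotide-shuffled
    reads drawn from the input library; ``seed`` makes the cutoff
    reproducible.
    """
    report = CleaningReport()
    for rec in records:
        report.reads_in[rec.individual_id] = report.reads_in.get(rec.individual_id, 0) + 1
        report.bp_in[rec.individual_id] = report.bp_in.get(rec.individual_id, 0) + len(rec)
        report.reads_kept.setdefault(rec.individual_id, 0)
        report.bp_kept.setdefault(rec.individual_id, 0)

    rng = np.random.default_rng(seed)
    have_adapters = bool(config.adapters)
    cutoff = (
        multimer_null_quantile(records, config, rng, n_null) if have_adapters else 1.0
    )

    kept: list[SequenceRecord] = []
    for rec in records:
        ind = rec.individual_id
        trimmed = trim_adapters(rec, config) if have_adapters else rec
        if trimmed.residues != rec.residues:
            report.adapter_trims[ind] = report.adapter_trims.get(ind, 0) + 1
        out = trim_poly_tail(trimmed, config)
        if out.residues != trimmed.residues:
            report.poly_trims[ind] = report.poly_trims.get(ind, 0) + 1
        if have_adapters:
            # score what survives trimming; a read consumed entirely by
            # adapter removal is scored as sequenced (the pure-multimer case)
            target = rec if out.residues == "N" and len(rec) > 1 else out
            score = tag_multimer_score(target, config.adapters, config.tag_k)
            if score > cutoff:
                report.discarded_as_multimer[ind] = (
                    report.discarded_as_multimer.get(ind, 0) + 1
                )
                continue
        if out.residues == "N" or len(out) < config.min_keep_len:
            continue
        kept.append(out)
        report.reads_kept[ind] += 1
        report.bp_kept[ind] += len(out)
    return kept, report
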