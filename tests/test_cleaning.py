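"""Adapter/poly-tail trimming and the multimer filter."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alleleflow.cleaning import (
    CleaningConfig,
    clean_library,
    dinucleotide_shuffle,
    tag_multimer_score,
    trim_adapters,
    trim_poly_tail,
)
from alleleflow.io import SequenceRecord

from conftest import random_seq

ADAPTER = "AAGCAGTGGTATCAACGCAGAGT"


def _read(seq, seq_id="r1", ind="i1"):
    return SequenceRecord(seq_id, ind, "g", seq)


@pytest.fixture
def config():
    return CleaningConfig(adapters={"smart": ADAPTER})


class TestTrimAdapters:
    def test_exact_adapter_at_5_prime(self, config):
        read = _read(ADAPTER + "ACGT" * 30)
        assert trim_adapters(read, config).residues == "ACGT" * 30

    def test_no_shared_kmers_unchanged(self, config):
        rng = np.random.default_rng(5)
        seq = "CT" * 60  # shares no 10-mer with the adapter
        read = _read(seq)
        assert trim_adapters(read, config).residues == seq

    def test_internal_hit_keeps_longer_fragment(self, config):
        rng = np.random.default_rng(7)
        left, right = random_seq(rng, 60), random_seq(rng, 37)
        read = _read(left + ADAPTER + right)
        expected = left if len(left) >= len(right) else right
        assert trim_adapters(read, config).residues == expected

    def test_mismatch_tolerance(self, config):
        mutated = "C" + ADAPTER[1:]  # 1 mismatch over 23 bp < 10%
        read = _read(mutated + "ACGT" * 30)
        assert trim_adapters(read, config).residues == "ACGT" * 30


class TestTrimPolyTail:
    def test_clean_3prime_a_tail(self, config):
        assert trim_poly_tail(_read("ACGTACGT" + "A" * 12), config).residues == "ACGTACGT"

    def test_5prime_t_run(self, config):
        core = "GATTACA" * 10
        assert trim_poly_tail(_read("T" * 10 + core), config).residues == core

    def test_interrupted_tail(self, config):
        assert trim_poly_tail(_read("ACGT" + "AAAAGAAAA"), config).residues == "ACGT"

    def test_short_run_untouched(self, config):
        seq = "GCGCGCGC" + "A" * 5
        assert trim_poly_tail(_read(seq), config).residues == seq


class TestMultimerScore:
    def test_pure_multimer_scores_one(self):
        read = _read(ADAPTER * 4)
        assert tag_multimer_score(read, {"a": ADAPTER}, 8) == 1.0

    def test_unrelated_read_scores_zero(self):
        rng = np.random.default_rng(11)
        read = _read("CT" * 100)
        assert tag_multimer_score(read, {"a": "G" * 30}, 8) == 0.0

    def test_half_adapter_matches_bruteforce(self):
        rng = np.random.default_rng(13)
        tail = random_seq(rng, len(ADAPTER))
        seq = ADAPTER + tail
        k = 8
        ref = set()
        from alleleflow.similarity import revcomp

        for src in (ADAPTER + ADAPTER, revcomp(ADAPTER + ADAPTER)):
            for i in range(len(src) - k + 1):
                ref.add(src[i : i + k])
        expected = sum(
            1 for i in range(len(seq) - k + 1) if seq[i : i + k] in ref
        ) / (len(seq) - k + 1)
        assert tag_multimer_score(_read(seq), {"a": ADAPTER}, k) == pytest.approx(expected)


def _clean_reads(rng, n=10, length=120):
    # GC-balanced random reads with no A/T runs long enough to trim
    reads = []
    while len(reads) < n:
        seq = random_seq(rng, length)
        probe = _read(seq, f"c{len(reads)}")
        cfg = CleaningConfig(adapters={"a": ADAPTER})
        if (
            trim_adapters(probe, cfg).residues == seq
            and trim_poly_tail(probe, cfg).residues == seq
        ):
            reads.append(probe)
    return reads


class TestCleanLibrary:
    def test_clean_reads_all_kept(self, config):
        rng = np.random.default_rng(17)
        reads = _clean_reads(rng)
        kept, report = clean_library(reads, config, seed=1)
        assert len(kept) == 10
        assert report.adapter_trims == {} and report.poly_trims == {}
        assert report.reads_kept["i1"] == 10

    def test_multimer_discarded(self, config):
        rng = np.random.default_rng(19)
        reads = _clean_reads(rng, n=9) + [_read(ADAPTER * 6, "bad")]
        kept, report = clean_library(reads, config, seed=1)
        assert {r.seq_id for r in kept} == {f"c{i}" for i in range(9)}
        assert report.discarded_as_multimer["i1"] == 1

    def test_short_after_trimming_dropped(self, config):
        read = _read(ADAPTER + "ACGTACGTACGTACGTACGT")  # 20 bp after trim
        kept, report = clean_library([read], config, seed=1)
        assert kept == []
        assert report.reads_kept["i1"] == 0

    def test_bp_conserved_or_reduced(self, config):
        rng = np.random.default_rng(23)
        reads = _clean_reads(rng) + [_read(ADAPTER + random_seq(rng, 100), "adp")]
        kept, report = clean_library(reads, config, seed=1)
        assert sum(report.bp_kept.values()) <= sum(report.bp_in.values())

    def test_min_keep_len_monotone(self, config):
        rng = np.random.default_rng(29)
        reads = [_read(random_seq(rng, int(l)), f"r{i}")
                 for i, l in enumerate(rng.integers(40, 200, size=30))]
        counts = []
        for min_len in (40, 80, 160):
            cfg = CleaningConfig(adapters={"a": ADAPTER}, min_keep_len=min_len)
            kept, _ = clean_library(reads, cfg, seed=1)
            counts.append(len(kept))
        assert counts == sorted(counts, reverse=True)

    def test_fdr_monotone_and_safe_at_small_fdr(self):
        """The FDR dial: a stricter (smaller) FDR never discards more, and
        clean reads sharing no adapter k-mers are never discarded."""
        rng = np.random.default_rng(31)
        reads = _clean_reads(rng, n=6) + [_read(ADAPTER * 6, "bad")]
        discards = []
        for fdr in (0.001, 0.05, 0.5):
            cfg = CleaningConfig(adapters={"a": ADAPTER}, tag_fdr=fdr)
            kept, report = clean_library(reads, cfg, seed=1)
            discards.append(sum(report.discarded_as_multimer.values()))
            # zero-score reads can never exceed a non-negative cutoff
            assert {f"c{i}" for i in range(6)} <= {r.seq_id for r in kept}
        assert discards == sorted(discards)

    def test_idempotent_on_cleaned_reads(self, config):
        rng = np.random.default_rng(37)
        raw = _clean_reads(rng, n=8) + [
            _read(ADAPTER + random_seq(rng, 90) + "A" * 15, "messy")
        ]
        once, _ = clean_library(raw, config, seed=1)
        twice, report = clean_library(once, config, seed=1)
        assert [r.residues for r in twice] == [r.residues for r in once]
        assert report.adapter_trims == {} and report.poly_trims == {}


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(0, 10_000))
def test_dinucleotide_shuffle_preserves_composition(seed):
    rng = np.random.default_rng(seed)
    seq = random_seq(rng, 60)
    shuffled = dinucleotide_shuffle(seq, rng)
    assert len(shuffled) == len(seq)
    assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]
    pairs = lambda s: Counter(zip(s, s[1:]))
    assert pairs(shuffled) == pairs(seq)
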