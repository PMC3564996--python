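"""K-mer index, candidate seeding, banded alignment, acceptance test."""

import numpy as np
import pytest

from alleleflow.io import SequenceRecord
from alleleflow.similarity import (
    AlignmentResult,
    banded_align,
    build_index,
    find_candidate_pairs,
    passes_allele_criteria,
    revcomp,
)

from _oracles import full_overlap_align, mutate_with_divergence
from conftest import random_seq


def _rec(seq, seq_id="s", ind="i"):
    return SequenceRecord(seq_id, ind, "g", seq)


class TestIndex:
    def test_posting_count(self):
        rng = np.random.default_rng(0)
        index = build_index([_rec(random_seq(rng, 20))], k=12)
        assert sum(len(v) for v in index.postings.values()) == 9

    def test_kmers_spanning_n_skipped(self):
        seq = "ACGTACGTACGT" + "N" + "ACGTACGTACGT"
        index = build_index([_rec(seq)], k=12)
        positions = {p for plist in index.postings.values() for _, p in plist}
        # any window overlapping the N (starts 1..12) is absent
        assert positions == {0, 13}

    def test_duplicate_sequences_two_postings(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 40)
        index = build_index([_rec(seq, "a"), _rec(seq, "b")], k=12)
        assert all(len(v) == 2 for v in index.postings.values())

    def test_k_range_enforced(self):
        with pytest.raises(ValueError):
            build_index([_rec("ACGT" * 10)], k=6)


class TestCandidates:
    def test_identical_pair_offset_zero(self):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 320)
        recs = [_rec(seq, "a"), _rec(seq, "b")]
        cands = find_candidate_pairs(build_index(recs), recs)
        assert [(c.query_id, c.subject_id, c.strand, c.offset) for c in cands] == [
            ("a", "b", "+", 0)
        ]

    def test_single_shared_kmer_below_threshold(self):
        rng = np.random.default_rng(3)
        shared = random_seq(rng, 12)  # exactly one shared 12-mer
        a = random_seq(rng, 80) + shared + random_seq(rng, 80)
        b = random_seq(rng, 80) + shared + random_seq(rng, 80)
        recs = [_rec(a, "a"), _rec(b, "b")]
        cands = find_candidate_pairs(build_index(recs), recs, min_shared_kmers=3)
        assert cands == []
        # with the threshold at 1 the same pair is seeded
        cands = find_candidate_pairs(build_index(recs), recs, min_shared_kmers=1)
        assert len(cands) == 1

    def test_reverse_complement_reported_minus(self):
        rng = np.random.default_rng(4)
        seq = random_seq(rng, 350)
        recs = [_rec(seq, "a"), _rec(revcomp(seq), "b")]
        cands = find_candidate_pairs(build_index(recs), recs)
        assert len(cands) == 1 and cands[0].strand == "-" and cands[0].offset == 0

    def test_full_recall_for_long_exact_overlaps(self):
        """Any pair sharing a >=300 bp exact stretch is always seeded."""
        rng = np.random.default_rng(5)
        recs = []
        expected = set()
        for i in range(12):
            core = random_seq(rng, 300 + int(rng.integers(0, 200)))
            a = random_seq(rng, int(rng.integers(0, 80))) + core
            tail = core + random_seq(rng, int(rng.integers(0, 80)))
            b = tail if i % 2 == 0 else revcomp(tail)
            recs += [_rec(a, f"a{i}"), _rec(b, f"b{i}")]
            expected.add((f"a{i}", f"b{i}"))
        for stride in (1, 4):
            cands = find_candidate_pairs(
                build_index(recs), recs, min_shared_kmers=3, stride=stride
            )
            found = {tuple(sorted((c.query_id, c.subject_id))) for c in cands}
            assert expected <= found


class TestBandedAlign:
    def test_identical_sequences(self):
        rng = np.random.default_rng(6)
        seq = random_seq(rng, 400)
        r = banded_align(_rec(seq, "a"), _rec(seq, "b"), 0)
        assert r.identity == 1.0 and r.aligned_len == 400
        assert (r.q_start, r.q_end, r.s_start, r.s_end) == (0, 400, 0, 400)

    def test_substitutions_identity(self):
        rng = np.random.default_rng(7)
        seq = random_seq(rng, 400)
        arr = list(seq)
        for pos in rng.choice(400, 8, replace=False):
            arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
        r = banded_align(_rec(seq, "a"), _rec("".join(arr), "b"), 0)
        assert r.identity == pytest.approx(0.98)
        assert r.aligned_len == 400

    def test_short_deletion_identity(self):
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 400)
        r = banded_align(_rec(seq, "a"), _rec(seq[:200] + seq[203:], "b"), 0)
        assert r.identity == pytest.approx((400 - 3) / 400)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        seq = random_seq(rng, 500)
        other = mutate_with_divergence(seq, 0.02, rng, n_indels=1)
        fwd = banded_align(_rec(seq, "a"), _rec(other, "b"), 0)
        rev = banded_align(_rec(other, "b"), _rec(seq, "a"), 0)
        assert fwd.identity == pytest.approx(rev.identity)
        assert fwd.aligned_len == rev.aligned_len

    def test_offset_overlap_geometry(self):
        rng = np.random.default_rng(10)
        seq = random_seq(rng, 600)
        a, b = seq[:450], seq[150:]
        r = banded_align(_rec(a, "a"), _rec(b, "b"), 150)
        assert r.identity == 1.0
        assert (r.q_start, r.q_end) == (150, 450)
        assert (r.s_start, r.s_end) == (0, 300)

    def test_no_overlap_raises(self):
        with pytest.raises(ValueError):
            banded_align(_rec("ACGT" * 30, "a"), _rec("ACGT" * 30, "b"), 500)

    def test_matches_unbanded_oracle(self):
        """Banded result equals the full-matrix DP within the band."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            length = int(rng.integers(300, 1500))
            a = random_seq(rng, length)
            b = mutate_with_divergence(a, 0.02, rng, n_indels=int(rng.integers(0, 3)))
            r = banded_align(_rec(a, "a"), _rec(b, "b"), 0)
            matches, aligned, score = full_overlap_align(a, b, 0)
            assert (r.matches, r.aligned_len, r.score) == (matches, aligned, score)


class TestAlleleCriteria:
    def _result(self, identity, aligned_len, q_len=400, s_len=400,
                q_start=0, q_end=400, s_start=0, s_end=400):
        return AlignmentResult(
            query_id="a", subject_id="b", q_len=q_len, s_len=s_len, strand="+",
            identity=identity, aligned_len=aligned_len,
            matches=int(identity * aligned_len),
            q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
        )

    def test_passing_alignment(self):
        assert passes_allele_criteria(self._result(0.96, 400))

    def test_identity_threshold(self):
        assert not passes_allele_criteria(self._result(0.94, 400))

    def test_length_threshold(self):
        r = self._result(0.96, 250, q_len=250, s_len=250, q_end=250, s_end=250)
        assert not passes_allele_criteria(r)

    def test_partial_overlap_coverage_rejected(self):
        # alignment stops 80 bp short of the mutual overlap end
        r = self._result(0.96, 320, q_end=320, s_end=320)
        assert not passes_allele_criteria(r)

    def test_end_slack_tolerated(self):
        r = self._result(0.96, 380, q_end=380, s_end=380)
        assert passes_allele_criteria(r)
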