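"""SNP calling, singleton masking, minimum haplotypes, genotype matrix."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alleleflow.clustering import ClusterConsensus, ClusterStatus
from alleleflow.io import SequenceRecord
from alleleflow.snp import (
    GenotypeMatrix,
    SNPSite,
    apply_min_allele_count,
    call_sites,
    genotype_matrix,
    map_members,
    member_site_vectors,
    min_haplotypes,
    write_vcf,
)

from _oracles import min_partition_haplotypes, mutate_with_divergence
from conftest import random_seq


def _cluster_with_members(consensus, members):
    """Cluster whose members all sit at offset 0 on the consensus."""
    cluster = ClusterConsensus(
        cluster_id="CL0",
        member_ids=set(members),
        status=ClusterStatus.OK,
        consensus=consensus,
        member_offsets={m: (0, "+") for m in members},
    )
    by_id = {m: SequenceRecord(m, f"ind_{m}", "g", seq) for m, seq in members.items()}
    cluster.members_by_individual = {
        rec.individual_id: [m] for m, rec in by_id.items()
    }
    return cluster, by_id


class TestMapMembers:
    def test_identical_member_calls_equal_consensus(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 400)
        cluster, by_id = _cluster_with_members(seq, {"a": seq})
        calls = map_members(cluster, by_id)
        assert calls["a"] == {i: seq[i] for i in range(400)}

    def test_low_identity_member_excluded(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 400)
        bad = mutate_with_divergence(seq, 0.11, rng)
        cluster, by_id = _cluster_with_members(seq, {"good": seq, "bad": bad})
        calls = map_members(cluster, by_id, min_identity=0.90)
        assert "good" in calls and "bad" not in calls

    def test_single_substitution_single_difference(self):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 400)
        variant = seq[:100] + ("A" if seq[100] != "A" else "C") + seq[101:]
        cluster, by_id = _cluster_with_members(seq, {"m": variant})
        calls = map_members(cluster, by_id)
        diffs = [p for p, b in calls["m"].items() if b != seq[p]]
        assert diffs == [100]


class TestCallSites:
    def test_identical_members_no_sites(self):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 300)
        cluster, by_id = _cluster_with_members(seq, {"a": seq, "b": seq})
        assert call_sites(cluster, map_members(cluster, by_id)) == []

    def test_single_variant_site_counts(self):
        rng = np.random.default_rng(4)
        seq = random_seq(rng, 300)
        alt = "A" if seq[50] != "A" else "G"
        variant = seq[:50] + alt + seq[51:]
        members = {f"m{i}": seq for i in range(4)}
        members["v"] = variant
        cluster, by_id = _cluster_with_members(seq, members)
        sites = call_sites(cluster, map_members(cluster, by_id))
        assert len(sites) == 1
        assert sites[0].pos == 50
        assert sites[0].alleles == {seq[50]: 4, alt: 1}

    def test_indel_only_column_not_a_site(self):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 300)
        deleted = seq[:150] + seq[153:]  # pure deletion, no substitution
        cluster, by_id = _cluster_with_members(seq, {"a": seq, "b": seq, "d": deleted})
        sites = call_sites(cluster, map_members(cluster, by_id))
        assert sites == []


class TestMinAlleleCount:
    def _site(self, counts):
        calls = {}
        i = 0
        for base, n in counts.items():
            for _ in range(n):
                calls[f"m{i}"] = base
                i += 1
        return SNPSite("CL0", 0, dict(counts), calls)

    def test_singleton_site_removed(self):
        assert apply_min_allele_count([self._site({"A": 5, "G": 1})]) == []

    def test_doubleton_site_retained(self):
        out = apply_min_allele_count([self._site({"A": 5, "G": 2})])
        assert len(out) == 1 and out[0].alleles == {"A": 5, "G": 2}

    def test_two_singletons_drop_site_entirely(self):
        assert apply_min_allele_count([self._site({"A": 3, "G": 1, "T": 1})]) == []

    def test_masked_allele_removed_from_calls(self):
        out = apply_min_allele_count([self._site({"A": 2, "G": 2, "T": 1})])
        assert len(out) == 1
        assert set(out[0].calls.values()) == {"A", "G"}
        assert all(c >= 2 for c in out[0].alleles.values())


class TestMinHaplotypes:
    def test_compatible_members_merge_to_one(self):
        vectors = {
            "a": ["A", None, "C"],
            "b": [None, "G", "C"],
            "c": ["A", "G", None],
        }
        count, haps, exact = min_haplotypes(vectors, "i1", "CL0")
        assert count == 1 and exact
        assert haps[0].states == ["A", "G", "C"]
        assert haps[0].support == ["a", "b", "c"]

    def test_conflicting_pair_gives_two(self):
        vectors = {"a": ["A", "C"], "b": ["A", "T"]}
        count, _, _ = min_haplotypes(vectors, "i1", "CL0")
        assert count == 2

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 10_000))
    def test_exact_mode_matches_partition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_members = int(rng.integers(2, 9))
        n_sites = int(rng.integers(1, 7))
        vectors = {}
        for i in range(n_members):
            states = [
                None if rng.random() < 0.35 else ("A", "C", "G", "T")[rng.integers(4)]
                for _ in range(n_sites)
            ]
            vectors[f"m{i}"] = states
        count, haps, exact = min_haplotypes(vectors, "i", "c")
        assert exact
        assert count == min_partition_haplotypes(list(vectors.values()))
        # merged groups are internally consistent by construction
        assert sum(len(h.support) for h in haps) == n_members

    def test_greedy_beyond_limit_flagged(self):
        vectors = {f"m{i}": ["A" if i % 2 else "C"] for i in range(5)}
        count, _, exact = min_haplotypes(vectors, "i", "c", exact_limit=3)
        assert not exact and count == 2


class TestGenotypeMatrix:
    def _solution(self):
        sites = [SNPSite("CL0", 10, {"A": 2, "G": 2}, {}),
                 SNPSite("CL0", 20, {"C": 2, "T": 2}, {})]
        cluster = ClusterConsensus(
            "CL0", {"x"}, status=ClusterStatus.RETAINED_SINGLE_LOCUS,
            consensus="A" * 30,
        )
        from alleleflow.snp import HaplotypeVector

        solutions = {
            "CL0": {
                "i1": (2, [
                    HaplotypeVector("i1", "CL0", ["A", "C"], ["m1"]),
                    HaplotypeVector("i1", "CL0", ["G", None], ["m2"]),
                ], True),
                "i2": (1, [HaplotypeVector("i2", "CL0", ["A", "C"], ["m3"])], True),
            }
        }
        return [cluster], {"CL0": sites}, solutions

    def test_genotype_shapes(self):
        clusters, sites, solutions = self._solution()
        matrix = genotype_matrix(
            clusters, sites, solutions, [("i1", "g1"), ("i2", "g1"), ("i3", "g2")]
        )
        assert matrix.get("i1", 0) == ("A", "G")       # two covering haplotypes
        assert matrix.get("i1", 1) == ("C",)           # one covers the site
        assert matrix.get("i2", 0) == ("A",)           # single haplotype
        assert matrix.get("i3", 0) is None             # absent individual
        assert matrix.sites == [("CL0", 10), ("CL0", 20)]

    def test_vcf_encoding(self, tmp_path):
        clusters, sites, solutions = self._solution()
        matrix = genotype_matrix(
            clusters, sites, solutions, [("i1", "g1"), ("i2", "g1"), ("i3", "g2")]
        )
        path = tmp_path / "out.vcf"
        write_vcf(matrix, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        data = [l.split("\t") for l in lines if not l.startswith("#")]
        assert len(data) == 2
        chrom, pos, _, ref, alt = data[0][:5]
        assert (chrom, pos, ref, alt) == ("CL0", "11", "A", "G")
        # i1 het 0/1, i2 half-missing 0/., i3 missing ./.
        assert data[0][9:] == ["0/1", "0/.", "./."]


def test_member_site_vectors_mask_non_retained_alleles():
    sites = [SNPSite("CL0", 5, {"A": 2, "G": 2}, {})]
    calls = {"m1": {5: "A"}, "m2": {5: "T"}, "m3": {}}
    vectors = member_site_vectors(sites, calls)
    assert vectors["m1"] == ["A"]
    assert vectors["m2"] == [None]  # T was masked out of the site
    assert vectors["m3"] == [None]
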