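"""End-to-end orchestration: unigenes in, genotype matrix out.

Stages: k-mer seeding -> banded pairwise alignment -> allele-candidate
acceptance (identity/length/full-overlap) -> single-linkage clustering ->
consensus / pseudo-reference -> member re-mapping and SNP calling ->
singleton-allele masking -> per-individual minimum haplotypes -> the
diploid (<=2 haplotypes per individual) locus filter -> genotype matrix.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from . import clustering, popgen, similarity, snp
from .clustering import ClusterConsensus, ClusterStatus
from .io import LibrarySet, write_fasta
from .similarity import AlignmentResult

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the workflow, with the standard defaults.

    The acceptance thresholds (95% identity, 300 bp, full overlap; 90%
    mapping identity; singletons removed; at most 2 haplotypes per diploid
    individual) are the workflow's defining parameters.
    """

    k: int = 12
    seed_stride: int = 4
    min_shared_kmers: int = 3
    band: int = 15
    min_identity: float = 0.95
    min_len: int = 300
    end_slack: int = 30
    consensus_min_identity: float = 0.95
    map_min_identity: float = 0.90
    min_allele_count: int = 2
    max_haplotypes: int = 2
    exact_limit: int = 12


@dataclass
class PipelineResult:
    library: LibrarySet
    config: PipelineConfig
    accepted_pairs: list[AlignmentResult]
    clusters: list[ClusterConsensus]
    pseudo_reference: list
    calls_by_cluster: dict[str, dict[str, dict[int, str]]]
    sites_by_cluster: dict[str, list[snp.SNPSite]]
    solutions: dict[str, dict]
    matrix: snp.GenotypeMatrix

    def clusters_by_status(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cluster in self.clusters:
            counts[cluster.status.value] = counts.get(cluster.status.value, 0) + 1
        return counts

    @property
    def n_retained_sites(self) -> int:
        return len(self.matrix.sites)

    def cluster_of(self, member_id: str) -> ClusterConsensus:
        if not hasattr(self, "_member_index"):
            self._member_index = {
                m: c for c in self.clusters for m in c.member_ids
            }
        return self._member_index[member_id]


def run_pipeline(library: LibrarySet, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the whole workflow on a loaded library set."""
    config = config or PipelineConfig()
    records = library.records
    records_by_id = {r.seq_id: r for r in records}

    logger.info("indexing %d unigenes (k=%d)", len(records), config.k)
    index = similarity.build_index(records, k=config.k)
    candidates = similarity.find_candidate_pairs(
        index,
        records,
        min_shared_kmers=config.min_shared_kmers,
        band=config.band,
        stride=config.seed_stride,
    )
    logger.info("%d candidate pairs", len(candidates))

    accepted: list[AlignmentResult] = []
    for cand in candidates:
        try:
            result = similarity.banded_align(
                records_by_id[cand.query_id],
                records_by_id[cand.subject_id],
                offset=cand.offset,
                band=config.band,
                strand=cand.strand,
            )
        except ValueError:
            continue
        if similarity.passes_allele_criteria(
            result,
            min_identity=config.min_identity,
            min_len=config.min_len,
            end_slack=config.end_slack,
        ):
            accepted.append(result)
    logger.info("%d accepted allele-candidate pairs", len(accepted))

    clusters = clustering.single_linkage([r.seq_id for r in records], accepted)
    for cluster in clusters:
        clustering.build_consensus(
            cluster,
            records_by_id,
            min_member_identity=config.consensus_min_identity,
            band=config.band,
        )
    pseudo_reference = clustering.build_pseudo_reference(clusters)
    logger.info(
        "%d clusters (%d with consensus)", len(clusters), len(pseudo_reference)
    )

    calls_by_cluster: dict[str, dict[str, dict[int, str]]] = {}
    sites_by_cluster: dict[str, list[snp.SNPSite]] = {}
    for cluster in clusters:
        if cluster.status != ClusterStatus.OK:
            continue
        calls = snp.map_members(
            cluster, records_by_id,
            min_identity=config.map_min_identity, band=config.band,
        )
        calls_by_cluster[cluster.cluster_id] = calls
        sites = snp.call_sites(cluster, calls)
        sites_by_cluster[cluster.cluster_id] = snp.apply_min_allele_count(
            sites, min_count=config.min_allele_count
        )

    solutions = snp.filter_single_locus(
        clusters,
        sites_by_cluster,
        calls_by_cluster,
        records_by_id,
        max_haplotypes=config.max_haplotypes,
        exact_limit=config.exact_limit,
    )
    matrix = snp.genotype_matrix(
        clusters,
        sites_by_cluster,
        solutions,
        library.individuals,
        max_haplotypes=config.max_haplotypes,
    )
    logger.info(
        "retained %d single-locus clusters, %d SNP sites",
        sum(c.status == ClusterStatus.RETAINED_SINGLE_LOCUS for c in clusters),
        len(matrix.sites),
    )
    return PipelineResult(
        library=library,
        config=config,
        accepted_pairs=accepted,
        clusters=clusters,
        pseudo_reference=pseudo_reference,
        calls_by_cluster=calls_by_cluster,
        sites_by_cluster=sites_by_cluster,
        solutions=solutions,
        matrix=matrix,
    )


def write_outputs(result: PipelineResult, out_dir: str | os.PathLike) -> None:
    """Write the standard output files of a pipeline run."""
    os.makedirs(out_dir, exist_ok=True)
    records_by_id = {r.seq_id: r for r in result.library.records}
    similarity.hit_table(result.accepted_pairs).to_csv(
        os.path.join(out_dir, "hits.tsv"), sep="\t", index=False
    )
    clustering.membership_table(result.clusters, records_by_id).to_csv(
        os.path.join(out_dir, "clusters.tsv"), sep="\t", index=False
    )
    if result.pseudo_reference:
        write_fasta(
            result.pseudo_reference, os.path.join(out_dir, "pseudo_reference.fasta")
        )
    snp.write_vcf(result.matrix, os.path.join(out_dir, "sites.vcf"))
    snp.haplotype_table(result.solutions).to_csv(
        os.path.join(out_dir, "haplotypes.tsv"), sep="\t", index=False
    )
    summaries = popgen.individual_summaries(
        result.matrix, dict(result.library.per_individual_bp)
    )
    popgen.summaries_table(summaries).to_csv(
        os.path.join(out_dir, "individual_summaries.tsv"), sep="\t", index=False
    )
    if len(result.library.individuals) >= 2:
        popgen.pairwise_overlap(result.matrix).to_csv(
            os.path.join(out_dir, "pairwise_overlap.tsv"), sep="\t"
        )
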