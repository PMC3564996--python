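"""SNP calling against the pseudo-reference and the diploid haplotype filter.

Each cluster member is re-aligned to its cluster consensus; consensus
columns where at least two distinct bases are observed are candidate SNP
sites (substitutions only — indel variation is ignored, since homopolymer
indel errors dominate long-read pyrosequencing data).  Variant alleles seen
only once across the whole dataset are masked as probable errors; a site is
retained only if at least two alleles each remain observed at least twice.

For every individual in a cluster, its member sequences are then merged
into the *minimum* number of haplotypes consistent with their SNP states:
two members conflict iff they disagree at some site where both have a call,
and the minimum haplotype count is the minimum number of pairwise
conflict-free groups (a minimum clique cover of the compatibility graph,
i.e. a minimum coloring of the conflict graph).  A diploid individual can
contribute at most two haplotypes to a single locus, so any cluster in
which some individual needs more than two is flagged as a likely collapsed
paralog family (multilocus) and excluded; the rest are retained as single
loci and their genotypes tabulated.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .clustering import ClusterConsensus, ClusterStatus
from .io import SequenceRecord
from .similarity import banded_align, revcomp

logger = logging.getLogger(__name__)

MISSING = None
BASES = "ACGT"


@dataclass
class SNPSite:
    """A variable consensus column with per-member base calls."""

    cluster_id: str
    pos: int  # 0-based on the cluster consensus
    alleles: dict[str, int]
    calls: dict[str, str]  # member_id -> base (missing members omitted)


@dataclass
class HaplotypeVector:
    """One individual's merged allele states over a cluster's SNP sites."""

    individual_id: str
    cluster_id: str
    states: list[str | None]
    support: list[str]


@dataclass
class GenotypeMatrix:
    """Retained single-locus clusters x SNP sites x individuals.

    ``genotype[(individual, site_index)]`` is a tuple of one base (a single
    covering haplotype), two bases sorted (both haplotypes cover the site),
    or absent for MISSING.
    """

    sites: list[tuple[str, int]]
    individuals: list[str]
    groups: dict[str, str]
    genotype: dict[tuple[str, int], tuple[str, ...]] = field(default_factory=dict)
    ref_alleles: dict[tuple[str, int], str] = field(default_factory=dict)
    site_alleles: dict[tuple[str, int], list[str]] = field(default_factory=dict)

    def get(self, individual: str, site_index: int):
        return self.genotype.get((individual, site_index), MISSING)

    def to_dataframe(self):
        import pandas as pd

        data = {}
        for j, site in enumerate(self.sites):
            column = []
            for ind in self.individuals:
                gt = self.get(ind, j)
                column.append("." if gt is None else "/".join(gt))
            data[f"{site[0]}:{site[1] + 1}"] = column
        return pd.DataFrame(data, index=self.individuals)


def map_members(
    cluster: ClusterConsensus,
    records_by_id: dict[str, SequenceRecord],
    min_identity: float = 0.90,
    band: int = 15,
) -> dict[str, dict[int, str]]:
    """Align every member back to the cluster consensus; per-column calls.

    Returns ``{member_id: {consensus_pos: base}}``; positions outside the
    member's aligned span or at member gap columns are simply absent
    (MISSING).  Members aligning below ``min_identity`` are excluded with a
    warning, mirroring a minimum-similarity mapping threshold.
    """
    if cluster.consensus is None:
        raise ValueError(f"{cluster.cluster_id}: no consensus to map against")
    cons_rec = SequenceRecord(cluster.cluster_id, "", "", cluster.consensus)
    calls: dict[str, dict[int, str]] = {}
    for mid in sorted(cluster.member_ids):
        offset, strand = cluster.member_offsets[mid]
        rec = records_by_id[mid]
        oriented = rec.residues if strand == "+" else revcomp(rec.residues)
        oriented_rec = SequenceRecord(mid, rec.individual_id, rec.group, oriented)
        result = banded_align(oriented_rec, cons_rec, offset=-offset, band=band)
        if result.identity < min_identity:
            logger.warning(
                "%s: member %s at %.3f < %.2f identity to consensus; "
                "excluded from SNP calling",
                cluster.cluster_id, mid, result.identity, min_identity,
            )
            continue
        member_map: dict[int, str] = {}
        for q_pos, s_pos, op in result.columns():
            if op in ("=", "X") and oriented[q_pos] in BASES:
                member_map[s_pos] = oriented[q_pos]
        calls[mid] = member_map
    return calls


def call_sites(
    cluster: ClusterConsensus, calls: dict[str, dict[int, str]]
) -> list[SNPSite]:
    """Consensus columns with >=2 distinct base calls (substitutions only)."""
    per_column: dict[int, dict[str, str]] = {}
    for mid, member_map in calls.items():
        for pos, base in member_map.items():
            per_column.setdefault(pos, {})[mid] = base
    sites = []
    for pos in sorted(per_column):
        column = per_column[pos]
        counts = Counter(column.values())
        if len(counts) >= 2:
            sites.append(
                SNPSite(
                    cluster_id=cluster.cluster_id,
                    pos=pos,
                    alleles=dict(counts),
                    calls=dict(column),
                )
            )
    return sites


def apply_min_allele_count(sites: list[SNPSite], min_count: int = 2) -> list[SNPSite]:
    """Mask rare alleles as probable errors; drop sites left monoallelic.

    Alleles observed fewer than ``min_count`` times are masked to MISSING in
    the calls; a site survives only if at least two distinct alleles each
    retain ``min_count`` observations.
    """
    retained = []
    for site in sites:
        keep = {b for b, c in site.alleles.items() if c >= min_count}
        if len(keep) < 2:
            continue
        calls = {m: b for m, b in site.calls.items() if b in keep}
        alleles = dict(Counter(calls.values()))
        retained.append(SNPSite(site.cluster_id, site.pos, alleles, calls))
    return retained


def _conflict_graph(vectors: list[list[str | None]]) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(range(len(vectors)))
    for i, j in itertools.combinations(range(len(vectors)), 2):
        for a, b in zip(vectors[i], vectors[j]):
            if a is not None and b is not None and a != b:
                graph.add_edge(i, j)
                break
    return graph


def _exact_min_coloring(graph: nx.Graph) -> dict[int, int] | None:
    """Exact minimum coloring by iterative-deepening backtracking."""
    nodes = sorted(graph.nodes, key=lambda n: -graph.degree(n))
    n = len(nodes)
    adj = {v: set(graph.adj[v]) for v in nodes}
    for k in range(1, n + 1):
        coloring: dict[int, int] = {}

        def assign(idx: int, used: int) -> bool:
            if idx == n:
                return True
            v = nodes[idx]
            neighbor_colors = {coloring[u] for u in adj[v] if u in coloring}
            # symmetry break: allow at most one brand-new color
            for color in range(min(used + 1, k)):
                if color in neighbor_colors:
                    continue
                coloring[v] = color
                if assign(idx + 1, max(used, color + 1)):
                    return True
                del coloring[v]
            return False

        if assign(0, 0):
            return coloring
    return None


def min_haplotypes(
    member_vectors: dict[str, list[str | None]],
    individual_id: str,
    cluster_id: str,
    exact_limit: int = 12,
) -> tuple[int, list[HaplotypeVector], bool]:
    """Merge one individual's members into a minimum set of haplotypes.

    Two members conflict iff they differ at a site where both are called;
    the result is the minimum number of pairwise conflict-free groups, each
    merged into one haplotype (union of called states).  Exact search up to
    ``exact_limit`` members, greedy largest-first coloring beyond (flagged
    by the returned ``exact`` boolean).
    """
    members = sorted(member_vectors)
    if not members:
        return 0, [], True
    vectors = [member_vectors[m] for m in members]
    graph = _conflict_graph(vectors)
    exact = len(members) <= exact_limit
    if exact:
        coloring = _exact_min_coloring(graph)
    else:
        logger.warning(
            "%s/%s: %d members > exact_limit=%d; greedy (approximate) "
            "haplotype minimization",
            cluster_id, individual_id, len(members), exact_limit,
        )
        coloring = nx.coloring.greedy_color(graph, strategy="largest_first")
    groups: dict[int, list[int]] = {}
    for node, color in coloring.items():
        groups.setdefault(color, []).append(node)
    n_sites = len(vectors[0]) if vectors else 0
    haplotypes = []
    for color in sorted(groups):
        idxs = groups[color]
        states: list[str | None] = [None] * n_sites
        for i in idxs:
            for s, base in enumerate(vectors[i]):
                if base is None:
                    continue
                if states[s] is None:
                    states[s] = base
                elif states[s] != base:
                    raise AssertionError(
                        "conflict-free group merged inconsistently "
                        f"({cluster_id}/{individual_id} site {s})"
                    )
        haplotypes.append(
            HaplotypeVector(
                individual_id=individual_id,
                cluster_id=cluster_id,
                states=states,
                support=sorted(members[i] for i in idxs),
            )
        )
    return len(haplotypes), haplotypes, exact


def member_site_vectors(
    sites: list[SNPSite], calls: dict[str, dict[int, str]]
) -> dict[str, list[str | None]]:
    """Per-member state vectors over the retained sites of one cluster."""
    positions = [site.pos for site in sites]
    retained = {site.pos: set(site.alleles) for site in sites}
    vectors: dict[str, list[str | None]] = {}
    for mid, member_map in calls.items():
        states: list[str | None] = []
        for pos in positions:
            base = member_map.get(pos)
            states.append(base if base in retained[pos] else None)
        vectors[mid] = states
    return vectors


def filter_single_locus(
    clusters: list[ClusterConsensus],
    sites_by_cluster: dict[str, list[SNPSite]],
    calls_by_cluster: dict[str, dict[str, dict[int, str]]],
    records_by_id: dict[str, SequenceRecord],
    max_haplotypes: int = 2,
    exact_limit: int = 12,
) -> dict[str, dict[str, tuple[int, list[HaplotypeVector], bool]]]:
    """Apply the <=``max_haplotypes``-per-individual locus filter.

    Updates each consensus-bearing cluster's status to MULTILOCUS or
    RETAINED_SINGLE_LOCUS and returns the per-cluster, per-individual
    haplotype solutions.  Clusters with no retained site are retained (they
    are simply monomorphic) and contribute no haplotypes.
    """
    solutions: dict[str, dict[str, tuple[int, list[HaplotypeVector], bool]]] = {}
    for cluster in clusters:
        if cluster.status != ClusterStatus.OK:
            continue
        sites = sites_by_cluster.get(cluster.cluster_id, [])
        calls = calls_by_cluster.get(cluster.cluster_id, {})
        if not sites:
            cluster.status = ClusterStatus.RETAINED_SINGLE_LOCUS
            solutions[cluster.cluster_id] = {}
            continue
        vectors = member_site_vectors(sites, calls)
        per_individual: dict[str, tuple[int, list[HaplotypeVector], bool]] = {}
        multilocus = False
        for ind, mids in sorted(cluster.members_by_individual.items()):
            ind_vectors = {m: vectors[m] for m in mids if m in vectors}
            if not ind_vectors:
                continue
            count, haps, exact = min_haplotypes(
                ind_vectors, ind, cluster.cluster_id, exact_limit
            )
            per_individual[ind] = (count, haps, exact)
            if count > max_haplotypes:
                multilocus = True
        cluster.status = (
            ClusterStatus.MULTILOCUS if multilocus else ClusterStatus.RETAINED_SINGLE_LOCUS
        )
        solutions[cluster.cluster_id] = per_individual
    return solutions


def genotype_matrix(
    clusters: list[ClusterConsensus],
    sites_by_cluster: dict[str, list[SNPSite]],
    solutions: dict[str, dict[str, tuple[int, list[HaplotypeVector], bool]]],
    individuals: list[tuple[str, str]],
    max_haplotypes: int = 2,
) -> GenotypeMatrix:
    """Collect per-individual genotypes over all retained single loci."""
    matrix = GenotypeMatrix(
        sites=[],
        individuals=[ind for ind, _ in individuals],
        groups=dict(individuals),
    )
    for cluster in clusters:
        if cluster.status != ClusterStatus.RETAINED_SINGLE_LOCUS:
            continue
        sites = sites_by_cluster.get(cluster.cluster_id, [])
        if not sites:
            continue
        base_index = len(matrix.sites)
        for local, site in enumerate(sites):
            key = (site.cluster_id, site.pos)
            matrix.sites.append(key)
            matrix.ref_alleles[key] = cluster.consensus[site.pos]
            matrix.site_alleles[key] = sorted(site.alleles)
        for ind, (count, haps, _exact) in solutions.get(cluster.cluster_id, {}).items():
            if count > max_haplotypes:
                raise ValueError(
                    f"{cluster.cluster_id}/{ind}: {count} haplotypes in a "
                    "retained cluster; run filter_single_locus first"
                )
            for local in range(len(sites)):
                observed = [
                    h.states[local] for h in haps if h.states[local] is not None
                ]
                if observed:
                    matrix.genotype[(ind, base_index + local)] = tuple(sorted(observed))
    return matrix


def write_vcf(
    matrix: GenotypeMatrix, path, source: str = "alleleflow"
) -> None:
    """Export retained sites as a minimal VCF v4.2.

    REF is the consensus base; genotypes are diploid, with single-haplotype
    observations written as half-missing (``i/.``) and MISSING as ``./.``.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.individuals),
    ]
    for j, key in enumerate(matrix.sites):
        cluster_id, pos = key
        ref = matrix.ref_alleles[key]
        alleles = matrix.site_alleles[key]
        alts = [b for b in alleles if b != ref]
        index = {ref: 0}
        for i, b in enumerate(alts, start=1):
            index[b] = i
        fields = [
            cluster_id,
            str(pos + 1),
            ".",
            ref,
            ",".join(alts) if alts else ".",
            ".",
            "PASS",
            ".",
            "GT",
        ]
        for ind in matrix.individuals:
            gt = matrix.get(ind, j)
            if gt is None:
                fields.append("./.")
            elif len(gt) == 1:
                fields.append(f"{index[gt[0]]}/.")
            else:
                a, b = sorted(index[x] for x in gt)
                fields.append(f"{a}/{b}")
        lines.append("\t".join(fields))
    with open(path, "w", newline="\n") as handle:
        handle.write("\n".join(lines) + "\n")


def haplotype_table(
    solutions: dict[str, dict[str, tuple[int, list[HaplotypeVector], bool]]]
):
    """All haplotype solutions as a DataFrame."""
    import pandas as pd

    rows = []
    for cluster_id in sorted(solutions):
        for ind in sorted(solutions[cluster_id]):
            count, haps, exact = solutions[cluster_id][ind]
            for idx, hap in enumerate(haps):
                rows.append(
                    {
                        "individual_id": ind,
                        "cluster_id": cluster_id,
                        "haplotype_index": idx,
                        "states": "".join(
                            "." if s is None else s for s in hap.states
                        ),
                        "support": ",".join(hap.support),
                        "mode": "exact" if exact else "greedy",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id", "cluster_id", "haplotype_index",
            "states", "support", "mode",
        ],
    )
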