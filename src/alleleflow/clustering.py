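"""Single-linkage clustering of unigenes and per-cluster consensus.

Accepted allele-candidate alignments form an undirected graph over unigenes;
its connected components are the putative loci (single linkage: one accepted
link merges two groups, so closely related paralogs and their alleles can be
pulled together — later stages detect and flag that).

For each cluster a consensus is built by a star multiple alignment: every
member is placed on the coordinates of the longest member (the anchor) by
propagating the pairwise strand/offset relations along a spanning tree of
the link graph, then banded-aligned to the anchor; the consensus base of a
column is the majority call, ties resolved toward the anchor.  A cluster
whose members cannot be reconciled — some member below the identity floor
against its own consensus, or an inconsistent strand assignment around a
cycle — yields no consensus and is discarded from downstream analysis.

The consensus sequences of all surviving clusters form the dataset's
"pseudo-reference": the alignment anchor used in place of a reference
genome.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict, deque
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx

from .io import SequenceRecord
from .similarity import AlignmentResult, banded_align, revcomp

logger = logging.getLogger(__name__)


class ClusterStatus(str, Enum):
    PENDING = "pending"
    OK = "ok"
    NO_CONSENSUS = "no_consensus"
    MULTILOCUS = "multilocus"
    RETAINED_SINGLE_LOCUS = "retained_single_locus"


@dataclass
class ClusterConsensus:
    """A single-linkage cluster with its consensus (pseudo-reference entry).

    ``member_offsets`` maps each member to ``(offset, strand)`` on consensus
    coordinates: oriented-member position ``p`` sits at consensus column
    ``p + offset`` (strand "-" means the member participates
    reverse-complemented).
    """

    cluster_id: str
    member_ids: set[str]
    members_by_individual: dict[str, list[str]] = field(default_factory=dict)
    status: ClusterStatus = ClusterStatus.PENDING
    consensus: str | None = None
    member_offsets: dict[str, tuple[int, str]] = field(default_factory=dict)
    links: list[AlignmentResult] = field(default_factory=list)


def single_linkage(
    all_ids: list[str], accepted_pairs: list[AlignmentResult]
) -> list[ClusterConsensus]:
    """Connected components of the accepted-pair graph, plus singletons.

    Cluster ids are assigned deterministically: components sorted by their
    lexicographically smallest member.
    """
    known = set(all_ids)
    graph = nx.Graph()
    graph.add_nodes_from(all_ids)
    for pair in accepted_pairs:
        if pair.query_id not in known or pair.subject_id not in known:
            raise ValueError(
                f"pair ({pair.query_id}, {pair.subject_id}) references unknown id"
            )
        graph.add_edge(pair.query_id, pair.subject_id)
    components = sorted(nx.connected_components(graph), key=min)
    by_member: dict[str, int] = {}
    clusters = []
    for idx, comp in enumerate(components):
        cluster = ClusterConsensus(
            cluster_id=f"CL{idx:06d}", member_ids=set(comp)
        )
        clusters.append(cluster)
        for member in comp:
            by_member[member] = idx
    for pair in accepted_pairs:
        clusters[by_member[pair.query_id]].links.append(pair)
    return clusters


def _directed_edges(links: list[AlignmentResult]):
    """Both directions of every link as (src, dst) -> (strand, offset, ...).

    A link states: a[p] corresponds to orient(b, strand)[p - offset].  The
    reverse direction is derived so placement can be propagated either way.
    """
    edges: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
    for r in links:
        a, b = r.query_id, r.subject_id
        la = r.q_len
        lb = r.s_len
        o = r.offset
        edges[a].append((b, r.strand, o))
        if r.strand == "+":
            edges[b].append((a, "+", -o))
        else:
            # rc(b)[q] ~ a[q + o]  =>  b[r'] ~ orient(a, "-")[r' - (o + lb - la)]
            edges[b].append((a, "-", o + lb - la))
    return edges


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _place_members(
    cluster: ClusterConsensus, lengths: dict[str, int], anchor: str
) -> dict[str, tuple[str, int]] | None:
    """BFS placement of every member relative to the anchor.

    Returns ``{member: (strand, offset_on_anchor)}`` or None when strand
    parity is inconsistent (an odd cycle of "-" links).
    """
    edges = _directed_edges(cluster.links)
    placement: dict[str, tuple[str, int]] = {anchor: ("+", 0)}
    queue = deque([anchor])
    while queue:
        a = queue.popleft()
        sa, ta = placement[a]
        for b, es, eo in edges.get(a, ()):
            if sa == "+":
                sb, tb = es, ta + eo
            else:
                sb = _flip(es)
                tb = ta - eo + lengths[a] - lengths[b]
            if b in placement:
                if placement[b][0] != sb:
                    return None
            else:
                placement[b] = (sb, tb)
                queue.append(b)
    return placement


def build_consensus(
    cluster: ClusterConsensus,
    records_by_id: dict[str, SequenceRecord],
    min_member_identity: float = 0.95,
    band: int = 15,
) -> ClusterConsensus:
    """Star alignment against the longest member; majority-rule consensus.

    Sets ``status`` to OK (consensus and member offsets populated) or
    NO_CONSENSUS (some member under ``min_member_identity`` against the
    consensus, counting its gap columns as disagreements, or inconsistent
    strand parity).  Consensus characters are always a base or N; member
    insertions relative to the anchor never become consensus columns.
    """
    if not cluster.member_ids:
        raise ValueError("empty cluster")
    members = sorted(cluster.member_ids)
    cluster.members_by_individual = {}
    for mid in members:
        ind = records_by_id[mid].individual_id
        cluster.members_by_individual.setdefault(ind, []).append(mid)

    if len(members) == 1:
        rec = records_by_id[members[0]]
        cluster.consensus = rec.residues
        cluster.member_offsets = {members[0]: (0, "+")}
        cluster.status = ClusterStatus.OK
        return cluster

    lengths = {mid: len(records_by_id[mid]) for mid in members}
    anchor = max(members, key=lambda m: (lengths[m], m))
    placement = _place_members(cluster, lengths, anchor)
    if placement is None:
        logger.info("%s: inconsistent strand parity", cluster.cluster_id)
        cluster.status = ClusterStatus.NO_CONSENSUS
        return cluster

    anchor_rec = records_by_id[anchor]
    la = lengths[anchor]
    votes: dict[int, Counter] = defaultdict(Counter)
    # member -> {anchor_coord: base or "-" for a gap within the aligned span}
    member_calls: dict[str, dict[int, str]] = {}
    for mid in members:
        strand, t = placement[mid]
        rec = records_by_id[mid]
        oriented = rec.residues if strand == "+" else revcomp(rec.residues)
        lm = len(oriented)
        calls: dict[int, str] = {}
        if t < la and t + lm > 0:  # overlaps the anchor: align
            oriented_rec = SequenceRecord(mid, rec.individual_id, rec.group, oriented)
            result = banded_align(oriented_rec, anchor_rec, offset=-t, band=band)
            for q_pos, s_pos, op in result.columns():
                if op in ("=", "X"):
                    calls[s_pos] = oriented[q_pos]
                elif op == "I":  # anchor base unmatched inside member span
                    calls[s_pos] = "-"
                # "D" columns are member insertions: no anchor column
            # overhangs beyond the aligned region: place directly
            for p in range(lm):
                c = p + t
                if c < 0 or c >= la:
                    calls[c] = oriented[p]
        else:  # no anchor overlap at all (chained placement): place directly
            for p in range(lm):
                calls[p + t] = oriented[p]
        member_calls[mid] = calls
        for coord, base in calls.items():
            if base in "ACGT":
                votes[coord][base] += 1

    lo = min(min(c.keys(), default=0) for c in member_calls.values())
    lo = min(lo, 0)
    hi = max(max(c.keys(), default=la - 1) for c in member_calls.values()) + 1
    hi = max(hi, la)
    consensus_chars = []
    for coord in range(lo, hi):
        counter = votes.get(coord)
        if not counter:
            consensus_chars.append("N")
            continue
        top = counter.most_common()
        best_count = top[0][1]
        tied = sorted(b for b, c in top if c == best_count)
        if len(tied) > 1 and 0 <= coord < la and anchor_rec.residues[coord] in tied:
            consensus_chars.append(anchor_rec.residues[coord])
        else:
            consensus_chars.append(tied[0])
    consensus = "".join(consensus_chars)

    for mid in members:
        calls = member_calls[mid]
        matches = 0
        denom = 0
        for coord, base in calls.items():
            cons = consensus[coord - lo]
            if base == "N" or cons == "N":
                continue
            denom += 1
            if base == cons:
                matches += 1
        identity = matches / denom if denom else 0.0
        if identity < min_member_identity:
            logger.info(
                "%s: member %s at %.3f identity to consensus -> no consensus",
                cluster.cluster_id, mid, identity,
            )
            cluster.status = ClusterStatus.NO_CONSENSUS
            return cluster

    cluster.consensus = consensus
    cluster.member_offsets = {
        mid: (placement[mid][1] - lo, placement[mid][0]) for mid in members
    }
    cluster.status = ClusterStatus.OK
    return cluster


def build_pseudo_reference(clusters: list[ClusterConsensus]) -> list[SequenceRecord]:
    """One FASTA record per consensus-bearing cluster."""
    out = []
    skipped = 0
    for cluster in clusters:
        if cluster.status == ClusterStatus.NO_CONSENSUS or cluster.consensus is None:
            skipped += 1
            continue
        out.append(SequenceRecord(cluster.cluster_id, "", "", cluster.consensus))
    if skipped:
        logger.info("pseudo-reference: %d cluster(s) without consensus excluded", skipped)
    return out


def membership_table(clusters: list[ClusterConsensus], records_by_id):
    """Cluster membership as a DataFrame (one row per member)."""
    import pandas as pd

    rows = []
    for cluster in clusters:
        for mid in sorted(cluster.member_ids):
            offset, strand = cluster.member_offsets.get(mid, (0, "+"))
            rows.append(
                {
                    "cluster_id": cluster.cluster_id,
                    "member_id": mid,
                    "individual_id": records_by_id[mid].individual_id,
                    "offset": offset,
                    "strand": strand,
                    "status": cluster.status.value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "member_id", "individual_id", "offset", "strand", "status"],
    )
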