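"""Synthetic multi-individual diploid transcriptome datasets with truth.

The generator emulates the population setting the workflow is designed
for: diploid, outbreeding individuals (two alleles per locus), gene
families containing paralog pairs from an old duplication (paralog
divergence well above allele divergence), standing allelic variation
shared across individuals, and uneven per-individual sequencing effort.

Allelic variation is modeled with a founder-haplotype pool: each gene copy
has four founder haplotypes mutated from the copy's ancestral sequence, and
every individual draws its two alleles uniformly (with replacement) from
those founders.  Shared founders make most variants recur across
individuals, so genuine polymorphism survives the singleton filter — the
outbred-population premise.  The founder mutation rate is solved so that
the *expected pairwise divergence between two random gametes* equals the
configured ``allele_divergence``.

Sequencing effort is modeled by ``capture_prob``: each haplotype of each
individual independently appears as a unigene with that probability,
optionally as a random fragment, optionally with substitution errors, and
in random orientation (assemblies do not preserve strand).

Every emitted unigene is recorded in a :class:`TruthSet` so that any stage
of the pipeline can be scored against known loci, alleles and genotypes.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .io import LibrarySet, SequenceRecord, write_fasta, write_manifest
from .similarity import revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions of one simulated dataset.

    Defaults describe a modest multi-individual survey: 8 diploid
    individuals in two groups, 175 expressed loci of which 1/7 are
    two-copy paralog families diverged 6% per site, allelic divergence 1%,
    and a 90% chance of recovering each haplotype as a unigene.
    """

    n_individuals: int = 8
    groups: dict[str, str] | None = None
    n_loci: int = 175
    paralog_fraction: float = 1.0 / 7.0
    paralog_divergence: float = 0.06
    allele_divergence: float = 0.01
    locus_len_range: tuple[int, int] = (400, 1500)
    capture_prob: float = 0.9
    fragmentation: tuple[int, int] | None = None
    error_rate: float = 0.0
    n_founders: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("paralog_fraction", "capture_prob", "error_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 <= self.allele_divergence < 0.75:
            raise ValueError("allele_divergence out of range")
        if not 0.0 <= self.paralog_divergence < 0.75:
            raise ValueError("paralog_divergence out of range")
        if self.locus_len_range[0] < 300:
            raise ValueError("locus_len_range minimum must be >= 300")
        if self.locus_len_range[0] > self.locus_len_range[1]:
            raise ValueError("locus_len_range must be (min, max)")
        if self.n_individuals < 1 or self.n_loci < 1:
            raise ValueError("n_individuals and n_loci must be positive")

    def individual_labels(self) -> list[tuple[str, str]]:
        if self.groups is not None:
            return list(self.groups.items())
        labels = []
        half = (self.n_individuals + 1) // 2
        for i in range(self.n_individuals):
            labels.append((f"I{i + 1:02d}", "G1" if i < half else "G2"))
        return labels


@dataclass
class UnigeneTruth:
    """Provenance of one emitted unigene."""

    seq_id: str
    individual_id: str
    locus: str
    copy_id: str  # locus name, or locus+copy suffix for paralog families
    allele_index: int  # 0 or 1: which of the individual's two gametes
    start: int  # fragment coordinates on the haplotype
    end: int
    strand: str  # emission orientation
    n_errors: int


@dataclass
class TruthSet:
    """Everything the simulator knows about a dataset."""

    config: SimulationConfig
    loci: list[str]
    paralog_families: dict[str, tuple[str, str]]  # locus -> its two copy ids
    copy_sequences: dict[str, str]  # copy_id -> ancestral copy sequence
    founders: dict[str, list[str]]  # copy_id -> founder haplotypes
    # (individual, copy_id) -> (founder index allele 0, founder index allele 1)
    gametes: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    unigenes: dict[str, UnigeneTruth] = field(default_factory=dict)

    def haplotype_sequence(self, individual: str, copy_id: str, allele: int) -> str:
        founder = self.gametes[(individual, copy_id)][allele]
        return self.founders[copy_id][founder]

    def emitted_for_copy(self, copy_id: str) -> list[UnigeneTruth]:
        if not self._by_copy:
            for u in self.unigenes.values():
                self._by_copy.setdefault(u.copy_id, []).append(u)
        return self._by_copy.get(copy_id, [])

    def true_snp_sites(self, copy_id: str, min_count: int = 2) -> dict[int, dict[str, int]]:
        """Polymorphic positions among this copy's *emitted* unigenes.

        Applies the same minimum-observation rule the pipeline uses: allele
        counts below ``min_count`` are masked, and a position qualifies only
        with >=2 surviving alleles.  Counts are over emitted unigene bases
        (fragmentation and errors included), i.e. what an error-free
        clustering of these unigenes would be able to observe.
        """
        from collections import Counter

        cached = self._site_cache.get((copy_id, min_count))
        if cached is not None:
            return cached
        columns: dict[int, Counter] = {}
        for truth in self.emitted_for_copy(copy_id):
            hap = self.haplotype_sequence(truth.individual_id, copy_id, truth.allele_index)
            emitted = self._emitted_sequence(truth, hap)
            for offset, base in enumerate(emitted):
                columns.setdefault(truth.start + offset, Counter())[base] += 1
        sites = {}
        for pos, counter in columns.items():
            keep = {b: c for b, c in counter.items() if c >= min_count}
            if len(keep) >= 2:
                sites[pos] = keep
        self._site_cache[(copy_id, min_count)] = sites
        return sites

    def _emitted_sequence(self, truth: UnigeneTruth, hap: str) -> str:
        """The unigene's bases in haplotype orientation and coordinates."""
        raw = self._raw[truth.seq_id]
        return raw if truth.strand == "+" else revcomp(raw)

    # filled by simulate_dataset: seq_id -> raw emitted residues
    _raw: dict[str, str] = field(default_factory=dict)
    _by_copy: dict[str, list[UnigeneTruth]] = field(default_factory=dict)
    _site_cache: dict = field(default_factory=dict)

    def true_genotype(self, individual: str, copy_id: str, pos: int) -> tuple[str, str]:
        h0 = self.haplotype_sequence(individual, copy_id, 0)[pos]
        h1 = self.haplotype_sequence(individual, copy_id, 1)[pos]
        return tuple(sorted((h0, h1)))

    def true_heterozygosity(self, individual: str) -> float:
        """Fraction of this individual's emitted-polymorphic sites that are het."""
        het = 0
        total = 0
        for copy_id in self.copy_sequences:
            if (individual, copy_id) not in self.gametes:
                continue
            for pos in self.true_snp_sites(copy_id):
                a, b = self.true_genotype(individual, copy_id, pos)
                total += 1
                het += a != b
        return het / total if total else 0.0


def founder_mutation_rate(allele_divergence: float, n_founders: int = 4) -> float:
    """Per-site founder mutation rate giving the target gamete divergence.

    Two random gametes come from distinct founders with probability
    ``1 - 1/n_founders``; two independently mutated founders differ at a
    site with probability ``2q(1-q) + (2/3)q^2``.  Solving
    ``(1 - 1/F) * (2q - (4/3)q^2) = d`` for q.
    """
    if allele_divergence == 0:
        return 0.0
    f = 1.0 - 1.0 / n_founders
    # (4/3) f q^2 - 2 f q + d = 0
    a, b, c = (4.0 / 3.0) * f, -2.0 * f, allele_divergence
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError(f"allele_divergence {allele_divergence} unattainable")
    return (-b - math.sqrt(disc)) / (2 * a)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute each site with probability ``rate`` (always to a new base)."""
    if rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n:
        for i in np.flatnonzero(hit):
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return "".join(arr), n


def simulate_dataset(
    config: SimulationConfig, out_dir: str | os.PathLike | None = None
) -> tuple[LibrarySet, TruthSet]:
    """Generate a dataset and its truth; optionally write FASTA + manifest.

    Fully deterministic given ``config.seed``.  When ``out_dir`` is given,
    one FASTA per individual, a ``manifest.tsv`` and a ``truth_unigenes.tsv``
    are written there.
    """
    rng = np.random.default_rng(config.seed)
    individuals = config.individual_labels()
    n_paralog = round(config.paralog_fraction * config.n_loci)

    loci = [f"L{i + 1:04d}" for i in range(config.n_loci)]
    paralog_families: dict[str, tuple[str, str]] = {}
    copy_sequences: dict[str, str] = {}
    for i, locus in enumerate(loci):
        length = int(rng.integers(config.locus_len_range[0], config.locus_len_range[1] + 1))
        ancestral = "".join(_BASES[rng.integers(0, 4, size=length)])
        if i < n_paralog:
            copy_a, copy_b = f"{locus}a", f"{locus}b"
            diverged, _ = _mutate(ancestral, config.paralog_divergence, rng)
            copy_sequences[copy_a] = ancestral
            copy_sequences[copy_b] = diverged
            paralog_families[locus] = (copy_a, copy_b)
        else:
            copy_sequences[locus] = ancestral

    q = founder_mutation_rate(config.allele_divergence, config.n_founders)
    founders = {
        copy_id: [_mutate(seq, q, rng)[0] for _ in range(config.n_founders)]
        for copy_id, seq in copy_sequences.items()
    }

    truth = TruthSet(
        config=config,
        loci=loci,
        paralog_families=paralog_families,
        copy_sequences=copy_sequences,
        founders=founders,
    )

    records: list[SequenceRecord] = []
    copy_to_locus = {}
    for locus in loci:
        if locus in paralog_families:
            for cid in paralog_families[locus]:
                copy_to_locus[cid] = locus
        else:
            copy_to_locus[locus] = locus

    for ind, grp in individuals:
        counter = 0
        for copy_id in sorted(copy_sequences):
            pair = (int(rng.integers(config.n_founders)), int(rng.integers(config.n_founders)))
            truth.gametes[(ind, copy_id)] = pair
            for allele in (0, 1):
                if rng.random() >= config.capture_prob:
                    continue
                hap = truth.founders[copy_id][pair[allele]]
                if config.fragmentation is not None:
                    fmin, fmax = config.fragmentation
                    length = min(int(rng.integers(fmin, fmax + 1)), len(hap))
                    start = int(rng.integers(0, len(hap) - length + 1))
                else:
                    start, length = 0, len(hap)
                fragment = hap[start : start + length]
                fragment, n_err = _mutate(fragment, config.error_rate, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                raw = fragment if strand == "+" else revcomp(fragment)
                counter += 1
                seq_id = f"{ind}_u{counter:05d}"
                records.append(SequenceRecord(seq_id, ind, grp, raw))
                truth.unigenes[seq_id] = UnigeneTruth(
                    seq_id=seq_id,
                    individual_id=ind,
                    locus=copy_to_locus[copy_id],
                    copy_id=copy_id,
                    allele_index=allele,
                    start=start,
                    end=start + length,
                    strand=strand,
                    n_errors=n_err,
                )
                truth._raw[seq_id] = raw

    library = LibrarySet(records=records, individuals=individuals)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        fasta_paths = {}
        for ind, _ in individuals:
            recs = [r for r in records if r.individual_id == ind]
            name = f"{ind}.fasta"
            fasta_paths[ind] = name
            if recs:
                write_fasta(recs, os.path.join(out_dir, name))
            else:
                with open(os.path.join(out_dir, name), "w") as handle:
                    handle.write("")
        write_manifest(individuals, fasta_paths, os.path.join(out_dir, "manifest.tsv"))
        _write_truth_table(truth, os.path.join(out_dir, "truth_unigenes.tsv"))

    return library, truth


def _write_truth_table(truth: TruthSet, path) -> None:
    import pandas as pd

    rows = [
        {
            "seq_id": u.seq_id,
            "individual_id": u.individual_id,
            "locus": u.locus,
            "copy_id": u.copy_id,
            "allele_index": u.allele_index,
            "start": u.start,
            "end": u.end,
            "strand": u.strand,
            "n_errors": u.n_errors,
        }
        for u in truth.unigenes.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _consensus_to_copy_pos(cluster, truth: TruthSet):
    """Per-cluster mapping from consensus coordinates to copy coordinates.

    Uses the placement of up to three members together with their truth
    provenance; returns ``(copy_id, fn)`` where ``fn(pos)`` gives the copy
    position for a consensus position (or None outside the member span).
    Substitution-only simulation makes the mapping affine per member.
    """
    from collections import Counter

    member_copies = Counter(
        truth.unigenes[m].copy_id for m in cluster.member_ids if m in truth.unigenes
    )
    if not member_copies:
        return None, None
    copy_id = member_copies.most_common(1)[0][0]
    # choose the longest member of the majority copy for the coordinate map
    candidates = [
        m for m in cluster.member_ids
        if m in truth.unigenes and truth.unigenes[m].copy_id == copy_id
        and m in cluster.member_offsets
    ]
    if not candidates:
        return copy_id, None
    spans = []
    for m in candidates:
        u = truth.unigenes[m]
        off, sm = cluster.member_offsets[m]
        length = u.end - u.start
        same = sm == u.strand
        spans.append((off, off + length, u.start, length, same))
    spans.sort(key=lambda s: -(s[1] - s[0]))

    def mapper(pos: int):
        for off, end, start, length, same in spans:
            if off <= pos < end:
                p = pos - off
                return start + p if same else start + length - 1 - p
        return None

    return copy_id, mapper


def score_against_truth(result, truth: TruthSet, min_count: int = 2) -> dict:
    """Score a pipeline run on simulated data against its truth set.

    Reported metrics:

    - ``locus_recovery``: fraction of emitted single-copy loci recovered as
      exactly one retained single-locus cluster holding all and only their
      unigenes;
    - ``mean_cluster_purity`` / ``mean_copy_completeness``: the usual
      clustering confusion summaries at the gene-copy level;
    - paralog detection: of families whose two copies co-cluster, how many
      are flagged multilocus (among those surviving consensus) or discarded
      at the consensus stage — both count as detected contamination;
    - ``false_multilocus``: single-copy loci wrongly flagged multilocus;
    - ``snp_precision`` / ``snp_recall`` on retained sites, against the
      polymorphic positions recoverable from the emitted unigenes under the
      same minimum-observation rule;
    - ``haplotype_count_accuracy``: share of (individual, retained cluster)
      pairs whose minimum haplotype count equals the number of distinct
      captured allele sequences;
    - ``het_mean_abs_error`` / ``het_max_abs_error``: per-individual
      observed heterozygosity vs. the true genotypes at the same sites.
    """
    from collections import Counter

    from .clustering import ClusterStatus

    clusters = result.clusters
    unigene_copy = {m: u.copy_id for m, u in truth.unigenes.items()}
    paralog_copies = {c for pair in truth.paralog_families.values() for c in pair}
    single_copies = [c for c in truth.copy_sequences if c not in paralog_copies]

    emitted_by_copy: dict[str, set[str]] = {}
    for m, cid in unigene_copy.items():
        emitted_by_copy.setdefault(cid, set()).add(m)

    # --- purity / completeness -------------------------------------------
    purities = []
    cluster_majority: dict[str, str] = {}
    for cluster in clusters:
        counts = Counter(unigene_copy[m] for m in cluster.member_ids)
        top_copy, top_n = counts.most_common(1)[0]
        cluster_majority[cluster.cluster_id] = top_copy
        purities.append(top_n / len(cluster.member_ids))
    completeness = []
    for cid, emitted in emitted_by_copy.items():
        best = max(
            (len(emitted & c.member_ids) for c in clusters), default=0
        )
        completeness.append(best / len(emitted))

    # --- exact recovery of single-copy loci ------------------------------
    retained = [c for c in clusters if c.status == ClusterStatus.RETAINED_SINGLE_LOCUS]
    retained_sets = {frozenset(c.member_ids): c for c in retained}
    recovered = 0
    denominator = 0
    false_multilocus = 0
    for cid in single_copies:
        emitted = emitted_by_copy.get(cid)
        if not emitted:
            continue
        denominator += 1
        if frozenset(emitted) in retained_sets:
            recovered += 1
        for cluster in clusters:
            if cluster.status == ClusterStatus.MULTILOCUS and set(
                unigene_copy[m] for m in cluster.member_ids
            ) == {cid}:
                false_multilocus += 1
                break

    # --- paralog co-clustering and flagging ------------------------------
    n_families = 0
    n_cocluster = 0
    n_flagged = 0
    n_discarded = 0
    n_consensus_ok = 0
    for locus, (copy_a, copy_b) in truth.paralog_families.items():
        ea, eb = emitted_by_copy.get(copy_a), emitted_by_copy.get(copy_b)
        if not ea or not eb:
            continue
        n_families += 1
        joint = None
        for cluster in clusters:
            if cluster.member_ids & ea and cluster.member_ids & eb:
                joint = cluster
                break
        if joint is None:
            continue
        n_cocluster += 1
        if joint.status == ClusterStatus.NO_CONSENSUS:
            n_discarded += 1
        else:
            n_consensus_ok += 1
            if joint.status == ClusterStatus.MULTILOCUS:
                n_flagged += 1

    # --- SNP precision / recall ------------------------------------------
    site_map: dict[tuple[str, int], tuple[str, int]] = {}
    pred_by_copy: dict[str, set[int]] = {}
    retained_copies: set[str] = set()
    for cluster in retained:
        copy_id, mapper = _consensus_to_copy_pos(cluster, truth)
        if copy_id is None or mapper is None:
            continue
        retained_copies.add(copy_id)
        for site in result.sites_by_cluster.get(cluster.cluster_id, []):
            pos = mapper(site.pos)
            if pos is not None:
                pred_by_copy.setdefault(copy_id, set()).add(pos)
                site_map[(cluster.cluster_id, site.pos)] = (copy_id, pos)
    tp = 0
    n_pred = 0
    n_truth = 0
    for copy_id in retained_copies:
        truth_sites = set(truth.true_snp_sites(copy_id, min_count))
        pred = pred_by_copy.get(copy_id, set())
        tp += len(pred & truth_sites)
        n_pred += len(pred)
        n_truth += len(truth_sites)
    snp_precision = tp / n_pred if n_pred else 1.0
    snp_recall = tp / n_truth if n_truth else 1.0

    # --- haplotype count accuracy ----------------------------------------
    hap_ok = 0
    hap_total = 0
    for cluster in retained:
        copy_id = cluster_majority[cluster.cluster_id]
        for ind, (count, _haps, _exact) in result.solutions.get(
            cluster.cluster_id, {}
        ).items():
            emitted_alleles = {
                truth.haplotype_sequence(ind, truth.unigenes[m].copy_id,
                                         truth.unigenes[m].allele_index)
                for m in cluster.members_by_individual.get(ind, [])
                if m in truth.unigenes
            }
            if not emitted_alleles:
                continue
            hap_total += 1
            hap_ok += count == len(emitted_alleles)

    # --- heterozygosity error over the same sites ------------------------
    het_errors = []
    individuals = result.matrix.individuals
    for ind in individuals:
        obs_het = 0
        true_het = 0
        n_two = 0
        for j, key in enumerate(result.matrix.sites):
            gt = result.matrix.get(ind, j)
            if gt is None or len(gt) != 2:
                continue
            mapped = site_map.get(key)
            if mapped is None:
                continue
            copy_id, pos = mapped
            if (ind, copy_id) not in truth.gametes:
                continue
            n_two += 1
            obs_het += gt[0] != gt[1]
            a, b = truth.true_genotype(ind, copy_id, pos)
            true_het += a != b
        if n_two:
            het_errors.append(abs(obs_het / n_two - true_het / n_two))
    return {
        "locus_recovery": recovered / denominator if denominator else 1.0,
        "n_single_copy_loci": denominator,
        "mean_cluster_purity": float(np.mean(purities)) if purities else 1.0,
        "mean_copy_completeness": float(np.mean(completeness)) if completeness else 1.0,
        "false_multilocus": false_multilocus,
        "n_paralog_families": n_families,
        "n_paralog_cocluster": n_cocluster,
        "n_paralog_consensus_ok": n_consensus_ok,
        "n_paralog_flagged": n_flagged,
        "n_paralog_discarded": n_discarded,
        "paralog_flag_sensitivity": (
            n_flagged / n_consensus_ok if n_consensus_ok else None
        ),
        "snp_precision": snp_precision,
        "snp_recall": snp_recall,
        "n_predicted_sites": n_pred,
        "n_true_sites": n_truth,
        "haplotype_count_accuracy": hap_ok / hap_total if hap_total else 1.0,
        "het_mean_abs_error": float(np.mean(het_errors)) if het_errors else 0.0,
        "het_max_abs_error": float(np.max(het_errors)) if het_errors else 0.0,
    }
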