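# Methods

This note documents the models, algorithms, parameters and design choices
behind `alleleflow`, and what the bundled simulator does and does not
emulate.

## Pairwise similarity and the allele criterion

**Seeding.**  All unigenes are indexed by overlapping 12-mers (k-mers
containing N are skipped).  For every sequence, its k-mers — and those of
its reverse complement, since assemblies do not preserve strand — are
looked up in the index; hits against another sequence vote for a diagonal
offset.  A pair becomes an alignment candidate when at least
`min_shared_kmers = 3` hits agree on one diagonal to within the band
(±15), and the modal diagonal becomes the alignment offset.  For speed the
query-side scan samples every 4th k-mer position (`seed_stride`); a pair
sharing a ≥300 bp exact stretch still yields ≳70 sampled hits, so the
stride cannot cost recall at the scales that matter.

**Alignment.**  Candidates are aligned by banded dynamic programming
around the seeded diagonal: match +1, mismatch −2, gap −3 (linear), band
half-width 15.  The alignment is anchored at the start of the overlap
implied by the offset and *free at the far end* (overlap semantics:
residues of the longer sequence beyond the overlap are not forced into
terminal gaps).  Identity is computed over **all** aligned columns, gap
columns included — a deliberately conservative denominator that penalizes
indel-rich alignments.  The kernel is numba-compiled; the test suite
checks it cell-for-cell against an independent full-matrix implementation.

**Acceptance.**  A pair is accepted as putative alleles iff identity
≥ 0.95, aligned length ≥ 300 columns, and the alignment covers the full
mutual overlap of the two sequences except for at most `end_slack = 30` bp
at each end.  The identity/length thresholds are the workflow's defining
parameters; the 30 bp slack operationalizes "aligned throughout the
overlap", for which no exact tolerance exists — it must be large enough to
absorb end-effects of the banded alignment and small enough that a
conserved-domain-only paralog alignment cannot sneak through.

## Clustering and consensus

Accepted pairs are edges of an undirected graph; single-linkage clusters
are its connected components (computed with networkx; deterministic
cluster ids by sorted smallest member).  Unpaired sequences become
singleton clusters whose consensus is the sequence itself.

Each multi-member cluster gets a **star alignment** against its longest
member (the anchor).  Member orientations and offsets are propagated from
the pairwise alignments along a BFS spanning tree; an inconsistent strand
assignment around a cycle (an odd cycle of "−" edges) is impossible for
real sequences and marks the cluster `no_consensus`.  Every member is then
banded-aligned to the anchor; per-column votes are tallied and the
consensus base is the majority, ties resolved toward the anchor's base
(making the consensus deterministic), zero-coverage columns are N, and
member insertions relative to the anchor never create consensus columns.
Finally each member's identity *to the consensus* is computed with its gap
columns counted as disagreements; any member below
`consensus_min_identity = 0.95` marks the cluster `no_consensus`.  This
operationalizes "the cluster aggregates sequences too dissimilar for a
single consensus": chained single-linkage clusters that drag in a
divergent paralog fail here and are discarded from downstream analysis.
Surviving consensus sequences form the pseudo-reference FASTA.

## SNP sites and the haplotype filter

Members are re-aligned to their cluster consensus and dropped (with a
warning) below `map_min_identity = 0.90`.  Per-consensus-column base calls
are recorded; member gap columns and positions outside the member's span
are MISSING.  A candidate site is any column with ≥2 distinct bases among
the calls — substitutions only; columns whose only variation is
gap/MISSING are not sites, and N is never an allele.

**Singleton masking.**  Alleles observed fewer than `min_allele_count = 2`
times across the whole dataset are masked to MISSING; a site is retained
only if ≥2 alleles each keep ≥2 observations.  Masking precedes the
two-allele test, so a three-allele site with two singleton alleles is
dropped entirely.  Rationale: a variant seen once cannot be distinguished
from a sequencing or assembly error without depth information.

**Minimum haplotypes.**  Within one individual and cluster, two members
*conflict* iff they disagree at some site where both are called.  The
individual's minimum haplotype count is the minimum number of pairwise
conflict-free groups — a minimum clique cover of the compatibility graph,
equivalently a minimum coloring of the conflict graph.  Pairwise
conflict-freedom (rather than sequential mergeability) makes the answer
order-independent, and guarantees consistent group merges.  Up to
`exact_limit = 12` members the exact minimum is found by iterative
deepening backtracking over the number of colors (validated in tests
against literal set-partition enumeration); beyond that a greedy
largest-first coloring is used and the solution flagged `greedy` in the
haplotype table.

**The diploid filter.**  A cluster is `multilocus` if any individual's
minimum count exceeds `max_haplotypes = 2` — more haplotypes than a
diploid can carry at one locus implies collapsed paralogs.  Everything
else is `retained_single_locus`; monomorphic clusters are retained and
simply contribute no sites.  `max_haplotypes` is a parameter so the tool
generalizes to other ploidies.

**Genotypes.**  Per individual and site: MISSING when no haplotype covers
the site, a single-base observation when exactly one does, an unordered
base pair when two do.  The VCF export encodes single observations as
half-missing genotypes (`i/.`), keeping the distinction between "one
allele seen" and "homozygous".

## Population summaries

Coverage fraction = covered sites / all retained sites.  Observed
heterozygosity = heterozygous pairs / sites with a two-haplotype
observation (single observations cannot witness heterozygosity and are
excluded from the denominator).  Pairwise overlap = fraction of all
retained sites covered in both individuals; its diagonal equals the
coverage fractions.  The group-coverage filter keeps sites with ≥
`min_per_group` genotyped individuals in *every* group, where "genotyped"
means any non-missing observation, including single-haplotype ones.
STRUCTURE export codes A/C/G/T as 1–4 and missing as −9, two rows per
individual, one leading marker-name line.

## Read cleaning

Stage order: adapter trimming → poly-A/T trimming → multimer filter →
length filter (≥50 bp).  Adapter occurrences (either strand, full adapter
slid across the read including partial end overlaps) count as hits at ≥10
matched bp and ≤10% mismatches; each hit splits the read and the longer
fragment survives, iterated to a fixed point.  Poly-A (3′) and poly-T (5′)
runs of ≥8 bases are trimmed, tolerating ≤2 single-base interruptions —
oligo-dT primers are deliberately "broken" with anchor bases, so real
tails are rarely pure.  Adapter-before-poly order reflects library
construction, where adapters flank the tails.

The multimer filter scores each read by the fraction of its 8-mers found
in the adapter set (including adapter–adapter junction k-mers on both
strands, so a read of concatenated primers scores 1.0).  The score of the
*trimmed* read (or of the original read when adapter trimming consumed it
entirely) is compared against an empirical null: 1,000
dinucleotide-shuffled library reads (Altschul–Erickson shuffle, preserving
dinucleotide composition and hence homopolymer structure), cutoff at the
`1 − tag_fdr` quantile (default FDR 0.01).  Under this rule the FDR is the
expected fraction of ordinary reads falsely discarded: a smaller FDR gives
a stricter (higher) cutoff and fewer discards.  This is an intentionally
simple stand-in for a full statistical read-contamination model: it keys
only on k-mer composition, which is exactly what separates multimer reads
from cDNA.

## The simulator

The generator emulates the population setting the workflow targets:
diploid outbred individuals, gene families with an old duplication, allele
divergence well below paralog divergence, shared standing variation, and
unequal sequencing effort.  Per locus: an ancestral sequence uniform over
A/C/G/T, length uniform in 400–1500 bp; a configurable fraction of loci
(default 1/7) is duplicated into a two-copy family, the second copy
mutated at `paralog_divergence = 0.06` per site.  Per gene copy, four
founder haplotypes are mutated from the copy sequence at a rate *q* solved
from `(1 − 1/4)(2q(1−q) + (2/3)q²) = allele_divergence`, so that the
expected divergence between two random gametes equals the configured value
(default 0.01).  Each individual draws its two alleles uniformly with
replacement from the founders — shared founders make variants recur across
individuals, which is what lets genuine polymorphism survive the singleton
filter, and yields heterozygosity of roughly ¾ of the per-site
polymorphism rate.  Each haplotype is emitted as a unigene with
probability `capture_prob` (default 0.9), optionally as a random fragment
(modeling assemblies that split loci through insufficient overlap),
optionally with per-base substitution errors, in random orientation.  All
randomness flows through one seeded generator; identical seeds give
byte-identical outputs.

What the simulator does **not** model: indels and homopolymer error
profiles, expression-level coverage variation, chimeric unigenes, more
than two copies per family, and population structure between groups (the
group labels partition individuals but all draw from the same founder
pool).  Passing end-to-end tests therefore demonstrate correctness of the
clustering/haplotype logic under clean substitution-only variation, not
robustness to assembly artifacts.

## Problem sizes and defaults

The standard study conditions used by the end-to-end tests and
`scripts/acceptance.py` are the simulator defaults: 8 individuals in two
groups of four, 150 single-copy loci plus 25 paralog pairs, 6%/1%
paralog/allele divergence, capture 0.9, no errors.  At these sizes the
whole pipeline (~2,900 unigenes, ~20,000 alignments) runs in about a
minute on one CPU.  At 6% divergence most paralog pairs correctly fail the
95% allele criterion and cluster apart; the families that do co-cluster at
a given seed are either discarded at the consensus stage or flagged
multilocus by the haplotype filter — all three outcomes are correct
handling of paralogy, and the truth scorer reports them separately.  The
acceptance script's group-coverage export uses `min_per_group = 3`, scaled
to the simulated four-individual groups (the default of 5 is meant for
larger cohorts).

## Degenerate inputs and numerical choices

Zero allele divergence yields zero retained sites and all clusters
retained-monomorphic.  Duplicated identical libraries change no cluster
boundaries and produce no heterozygous calls.  Cleaning is idempotent on
cleaned reads.  Empty clusters, manifests with missing columns or
duplicate individuals, pairs referencing unknown ids, and efforts naming
unknown individuals raise explicit errors.  Ties are always broken
deterministically (consensus: anchor base, then lexicographic; cluster
ids: sorted smallest member; modal seeding diagonal: smallest diagonal),
so every stage is reproducible bit-for-bit.
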