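# alleleflow

Reference-free allele clustering and SNP discovery for multi-individual
transcriptome assemblies.

## The problem

Population genomics in non-model organisms often starts from *de novo*
transcriptome assemblies of many individuals and no reference genome.
Calling SNPs in that setting faces a specific trap: in an outbred diploid,
the two alleles of a locus can be as divergent as two recently duplicated
gene copies (paralogs), so no similarity threshold alone can tell "two
alleles of one locus" from "two collapsed loci".  Read depth does not help
either — transcriptome (especially normalized cDNA) coverage reflects
expression and library chemistry, not copy number.

`alleleflow` implements a workflow that resolves this with *population
information* instead of depth:

1. **Similarity search** — all unigenes (contigs and singleton reads) from
   all individuals are compared pairwise via k-mer seeded banded alignment;
   a pair is accepted as putative alleles at ≥95% identity over ≥300
   aligned bp, provided the alignment spans the full mutual overlap of the
   two sequences (true alleles align throughout their overlap; paralogs
   often do not).
2. **Single-linkage clustering** — accepted pairs define a graph whose
   connected components are putative loci.
3. **Consensus / pseudo-reference** — each cluster gets a star-alignment
   majority consensus; clusters that aggregate sequences too dissimilar for
   a single consensus (any member <95% identical to it) are discarded.  The
   surviving consensus sequences form a "pseudo-reference" that stands in
   for the missing genome.
4. **SNP calling** — members are re-aligned to their consensus (≥90%
   identity required); consensus columns with ≥2 distinct bases are SNP
   candidates; variant alleles observed only once across the whole dataset
   are masked as probable errors, and a site is kept only if ≥2 alleles
   each remain observed ≥2 times.
5. **The diploid haplotype filter** — for each individual in each cluster,
   its sequences are merged into the *minimum* number of SNP haplotypes
   (minimum clique cover of the compatibility graph; exact for ≤12
   sequences).  A diploid can carry at most two haplotypes per locus, so a
   cluster in which any individual needs more than two is flagged as a
   collapsed paralog family ("multilocus") and excluded.  The rest are
   retained single loci and their genotypes tabulated.
6. **Population summaries** — per-individual SNP coverage and observed
   heterozygosity, pairwise SNP-position overlap between libraries, a
   genotyped-in-≥*n*-individuals-per-group site filter, and export in
   STRUCTURE's two-rows-per-individual format and minimal VCF.

The package also provides a pre-assembly **read cleaner** (adapter/primer
trimming, interrupted poly-A/T tail trimming, and removal of primer
multimer reads via a dinucleotide-shuffled empirical null at a configurable
false-discovery rate) and a **synthetic diploid transcriptome simulator**
with complete truth tables (loci, paralog families, founder alleles, per
individual genotypes), so every stage is testable end to end without any
external data.

## Worked example

Simulate four diploid individuals at twenty expressed loci (a seventh of
them duplicated gene families), then run the full workflow:

```bash
$ alleleflow simulate --out-dir sim --individuals 4 --loci 20 --seed 11
wrote 166 unigenes for 4 individuals to sim

$ alleleflow run --manifest sim/manifest.tsv --out-dir out
23 clusters (23 retained single-locus, 0 multilocus, 0 no consensus); 361 SNP sites -> out
```

The 20 simulated loci include 3 two-copy paralog families; at their 6%
divergence the copies fail the 95% allele criterion and cluster apart, so
17 + 6 = 23 clusters are expected and all pass the ≤2-haplotypes diploid
filter.  `out/` then contains the pseudo-reference FASTA, cluster
membership and haplotype tables, a minimal VCF of the 361 retained SNP
sites, and per-individual summaries:

```
individual_id  effort_bp  sites_covered  coverage_fraction  het_observed
I01            37597      361            1.0                0.6289592760180995
I02            41046      361            1.0                0.7114427860696517
```

`coverage_fraction` is the share of all retained SNP positions observed in
that individual (1.0 here because every haplotype was captured);
`het_observed` is the fraction of its two-haplotype sites carrying two
different alleles — high, as expected for an outbred diploid drawing
alleles from a shared founder pool.

The same stages are available as library functions
(`alleleflow.run_pipeline`, `alleleflow.simulate_dataset`,
`alleleflow.score_against_truth`, ...) for programmatic use.

## Limitations

Substitution SNPs only (indels are deliberately ignored — homopolymer
indel errors dominate long-read pyrosequencing data); no depth- or
quality-aware genotype likelihoods (the workflow exists precisely for data
where depth is uninformative); STRUCTURE itself is not run, only its input
is produced.  See `docs/methods.md` for the model, parameter and design
details.
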