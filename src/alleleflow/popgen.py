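"""Population-genetic summaries of the genotype matrix.

Per-individual SNP coverage and observed heterozygosity both scale with
sequencing effort in transcriptome data, so these summaries are reported
alongside each individual's cleaned base-pair total.  Pairwise overlap
measures how many SNP positions two libraries share, the limiting factor
for any cross-individual analysis.  A per-group coverage filter selects
sites genotyped broadly enough for population-structure inference, and the
filtered matrix can be exported in STRUCTURE's two-rows-per-individual
input format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snp import GenotypeMatrix

logger = logging.getLogger(__name__)

STRUCTURE_CODES = {"A": 1, "C": 2, "G": 3, "T": 4}
STRUCTURE_MISSING = -9


@dataclass
class IndividualSummary:
    individual_id: str
    effort_bp: int
    sites_covered: int
    coverage_fraction: float
    het_observed: float


def individual_summaries(
    matrix: GenotypeMatrix, efforts: dict[str, int]
) -> list[IndividualSummary]:
    """Coverage and observed heterozygosity per individual.

    ``coverage_fraction`` is the share of all retained SNP positions with
    any observation; ``het_observed`` is the share of sites with a
    two-haplotype observation at which the two alleles differ.
    """
    unknown = set(efforts) - set(matrix.individuals)
    if unknown:
        raise ValueError(f"efforts name unknown individual(s): {sorted(unknown)}")
    n_sites = len(matrix.sites)
    out = []
    for ind in matrix.individuals:
        covered = 0
        two_obs = 0
        het = 0
        for j in range(n_sites):
            gt = matrix.get(ind, j)
            if gt is None:
                continue
            covered += 1
            if len(gt) == 2:
                two_obs += 1
                if gt[0] != gt[1]:
                    het += 1
        if two_obs == 0:
            logger.warning("%s: no two-haplotype observations; het reported as 0", ind)
        out.append(
            IndividualSummary(
                individual_id=ind,
                effort_bp=efforts.get(ind, 0),
                sites_covered=covered,
                coverage_fraction=covered / n_sites if n_sites else 0.0,
                het_observed=het / two_obs if two_obs else 0.0,
            )
        )
    return out


def summaries_table(summaries: list[IndividualSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual_id": s.individual_id,
                "effort_bp": s.effort_bp,
                "sites_covered": s.sites_covered,
                "coverage_fraction": s.coverage_fraction,
                "het_observed": s.het_observed,
            }
            for s in summaries
        ]
    )


def _coverage_bool(matrix: GenotypeMatrix) -> np.ndarray:
    inds = matrix.individuals
    covered = np.zeros((len(inds), len(matrix.sites)), dtype=bool)
    for i, ind in enumerate(inds):
        for j in range(len(matrix.sites)):
            covered[i, j] = matrix.get(ind, j) is not None
    return covered


def pairwise_overlap(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Fraction of all retained SNP positions observed in both individuals.

    Returned as a symmetric DataFrame ordered by individual_id; the
    diagonal equals each individual's coverage fraction.
    """
    if len(matrix.individuals) < 2:
        raise ValueError("pairwise overlap needs >= 2 individuals")
    inds = sorted(matrix.individuals)
    order = [matrix.individuals.index(i) for i in inds]
    covered = _coverage_bool(matrix)[order]
    n_sites = len(matrix.sites)
    if n_sites == 0:
        values = np.zeros((len(inds), len(inds)))
    else:
        values = (covered.astype(np.int64) @ covered.T.astype(np.int64)) / n_sites
    return pd.DataFrame(values, index=inds, columns=inds)


def filter_by_group_coverage(
    matrix: GenotypeMatrix, min_per_group: int = 5
) -> GenotypeMatrix:
    """Keep sites genotyped in at least ``min_per_group`` individuals of
    every group."""
    groups: dict[str, list[str]] = {}
    for ind in matrix.individuals:
        groups.setdefault(matrix.groups[ind], []).append(ind)
    for grp, members in groups.items():
        if len(members) < min_per_group:
            logger.warning(
                "group %s has only %d member(s) < min_per_group=%d; "
                "no site can pass", grp, len(members), min_per_group,
            )
    keep: list[int] = []
    for j in range(len(matrix.sites)):
        ok = all(
            sum(1 for ind in members if matrix.get(ind, j) is not None) >= min_per_group
            for members in groups.values()
        )
        if ok:
            keep.append(j)
    out = GenotypeMatrix(
        sites=[matrix.sites[j] for j in keep],
        individuals=list(matrix.individuals),
        groups=dict(matrix.groups),
    )
    for new_j, j in enumerate(keep):
        key = matrix.sites[j]
        out.ref_alleles[key] = matrix.ref_alleles[key]
        out.site_alleles[key] = matrix.site_alleles[key]
        for ind in matrix.individuals:
            gt = matrix.get(ind, j)
            if gt is not None:
                out.genotype[(ind, new_j)] = gt
    return out


def export_structure(matrix: GenotypeMatrix, path) -> None:
    """Write the genotype matrix in STRUCTURE two-rows-per-individual format.

    Row layout: a marker-name header line, then for each individual two
    rows of ``label pop_code allele_code...`` with A/C/G/T coded 1-4 and
    missing as -9.  Single-haplotype observations emit the observed base on
    the first row and -9 on the second.
    """
    pop_codes = {g: i + 1 for i, g in enumerate(sorted(set(matrix.groups.values())))}
    lines = [" ".join(f"{c}:{p + 1}" for c, p in matrix.sites)]
    for ind in matrix.individuals:
        rows: tuple[list[str], list[str]] = ([], [])
        for j in range(len(matrix.sites)):
            gt = matrix.get(ind, j)
            if gt is None:
                first = second = STRUCTURE_MISSING
            elif len(gt) == 1:
                first, second = STRUCTURE_CODES[gt[0]], STRUCTURE_MISSING
            else:
                first, second = STRUCTURE_CODES[gt[0]], STRUCTURE_CODES[gt[1]]
            rows[0].append(str(first))
            rows[1].append(str(second))
        prefix = [ind, str(pop_codes[matrix.groups[ind]])]
        lines.append(" ".join(prefix + rows[0]))
        lines.append(" ".join(prefix + rows[1]))
    with open(path, "w", newline="\n") as handle:
        handle.write("\n".join(lines) + "\n")
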