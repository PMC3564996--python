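"""FASTA and sample-manifest input/output.

Every sequence in the workflow carries provenance: the individual it was
sequenced from and that individual's group (typically a region or continent
label).  A *manifest* is a TSV with columns ``individual_id``, ``group`` and
``fasta_path`` — one row per individual library.  Loading a manifest pools all
libraries into a single :class:`LibrarySet`, the unit the clustering stages
operate on.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
#: IUPAC ambiguity codes (and anything else unexpected) collapse to N.
_AMBIGUITY = frozenset("RYSWKMBDHV")

MANIFEST_COLUMNS = ("individual_id", "group", "fasta_path")


class ManifestError(ValueError):
    """Raised for malformed manifests (missing columns, duplicate rows)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One read or unigene with its owning individual and group label."""

    seq_id: str
    individual_id: str
    group: str
    residues: str
    source: str = "unigene"  # "raw_read" | "unigene"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.seq_id}: empty residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LibrarySet:
    """All sequences of a multi-individual dataset, with provenance."""

    records: list[SequenceRecord]
    individuals: list[tuple[str, str]]  # (individual_id, group), manifest order

    per_individual_bp: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = {ind for ind, _ in self.individuals}
        for rec in self.records:
            if rec.individual_id not in known:
                raise ValueError(
                    f"record {rec.seq_id} references unknown individual "
                    f"{rec.individual_id!r}"
                )
        if not self.per_individual_bp:
            bp = {ind: 0 for ind, _ in self.individuals}
            for rec in self.records:
                bp[rec.individual_id] += len(rec)
            self.per_individual_bp = bp

    @property
    def groups(self) -> dict[str, str]:
        return dict(self.individuals)

    def __len__(self) -> int:
        return len(self.records)


def normalize_residues(raw: str, seq_id: str = "?") -> str:
    """Upper-case, U->T, collapse ambiguity codes to N.

    Anything outside ``ACGTN`` after that is rejected.
    """
    seq = raw.upper().replace("U", "T")
    if set(seq) - VALID_BASES:
        converted = []
        n_amb = 0
        for ch in seq:
            if ch in VALID_BASES:
                converted.append(ch)
            elif ch in _AMBIGUITY:
                converted.append("N")
                n_amb += 1
            else:
                raise ValueError(f"{seq_id}: invalid residue {ch!r}")
        logger.warning(
            "%s: %d ambiguity residue(s) converted to N", seq_id, n_amb
        )
        seq = "".join(converted)
    return seq


def _parse_attrs(description: str) -> dict[str, str]:
    attrs = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, value = token.split("=", 1)
            attrs[key] = value
    return attrs


def read_fasta(
    path: str | os.PathLike,
    individual_id: str | None = None,
    group: str | None = None,
    source: str = "unigene",
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    ``individual=`` / ``group=`` header attributes written by
    :func:`write_fasta` are recovered unless overridden by the arguments.
    """
    records: list[SequenceRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read FASTA {path}: {exc}") from exc
    for bio in parsed:
        attrs = _parse_attrs(bio.description)
        records.append(
            SequenceRecord(
                seq_id=bio.id,
                individual_id=individual_id or attrs.get("individual", ""),
                group=group if group is not None else attrs.get("group", ""),
                residues=normalize_residues(str(bio.seq), bio.id),
                source=source,
            )
        )
    return records


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records as 60-column FASTA with provenance in the header.

    Header form: ``>seq_id individual=<id> group=<g>`` (attributes omitted
    when empty, e.g. for pseudo-reference consensus records).
    """
    if not records:
        raise ValueError("refusing to write an empty FASTA")
    bio_records = []
    for rec in records:
        parts = []
        if rec.individual_id:
            parts.append(f"individual={rec.individual_id}")
        if rec.group:
            parts.append(f"group={rec.group}")
        bio_records.append(
            _BioRecord(Seq(rec.residues), id=rec.seq_id, description=" ".join(parts))
        )
    with open(path, "w", newline="\n") as handle:
        SeqIO.write(bio_records, handle, "fasta")


def load_manifest(path: str | os.PathLike, source: str = "unigene") -> LibrarySet:
    """Load a sample manifest and all FASTA libraries it points to.

    Relative ``fasta_path`` entries are resolved against the manifest's own
    directory.  ``seq_id`` collisions across libraries are namespaced by
    prefixing ``<individual_id>|``.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise ManifestError(f"cannot read manifest {path}: {exc}") from exc
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise ManifestError(f"manifest missing column(s): {sorted(missing)}")
    if table["individual_id"].duplicated().any():
        dupes = table["individual_id"][table["individual_id"].duplicated()]
        raise ManifestError(f"duplicate individual_id rows: {sorted(set(dupes))}")

    base = os.path.dirname(os.path.abspath(str(path)))
    individuals: list[tuple[str, str]] = []
    records: list[SequenceRecord] = []
    seen_ids: set[str] = set()
    for row in table.itertuples(index=False):
        ind, grp = row.individual_id, row.group
        fasta = row.fasta_path
        if not os.path.isabs(fasta):
            fasta = os.path.join(base, fasta)
        individuals.append((ind, grp))
        for rec in read_fasta(fasta, individual_id=ind, group=grp, source=source):
            seq_id = rec.seq_id
            if seq_id in seen_ids:
                seq_id = f"{ind}|{seq_id}"
                logger.warning(
                    "seq_id collision: %s renamed to %s", rec.seq_id, seq_id
                )
            seen_ids.add(seq_id)
            records.append(
                SequenceRecord(seq_id, ind, grp, rec.residues, source=source)
            )
    return LibrarySet(records=records, individuals=individuals)


def write_manifest(
    individuals: list[tuple[str, str]],
    fasta_paths: dict[str, str],
    path: str | os.PathLike,
) -> None:
    """Write a manifest TSV for the given (individual, group) pairs."""
    frame = pd.DataFrame(
        {
            "individual_id": [ind for ind, _ in individuals],
            "group": [grp for _, grp in individuals],
            "fasta_path": [fasta_paths[ind] for ind, _ in individuals],
        }
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
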