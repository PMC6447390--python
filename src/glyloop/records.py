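"""Core record types, FASTA ingestion and TSV report writing.

Protein records hold residues over the 20 standard amino acids plus ``X``
(unknown, the translation of gap-derived ``N`` runs).  CDS records hold raw
nucleotide spans as found in draft assemblies, including ``N``.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, fields as dc_fields, is_dataclass, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(STANDARD_RESIDUES + "X")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

_CODON_TABLE = dict(standard_dna_table.forward_table)
_CODON_TABLE.update({c: "*" for c in STOP_CODONS})


class GeneLabel(str, Enum):
    """Paralog labels assigned by genomic position within the locus."""

    LOR1 = "LOR1"
    LOR2 = "LOR2"
    LOR2B = "LOR2B"
    LOR3 = "LOR3"
    LOR3B = "LOR3B"
    OTHER = "OTHER"

    @classmethod
    def from_token(cls, token: str) -> "GeneLabel":
        try:
            return cls(token.upper())
        except ValueError:
            return cls.OTHER


@dataclass(frozen=True)
class ProteinRecord:
    """One loricrin-like protein with species and paralog labels."""

    id: str
    residues: str
    species_code: str = ""
    gene_label: GeneLabel = GeneLabel.OTHER
    source_note: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        residues = self.residues.upper()
        # A single terminal stop marker from translation is tolerated and
        # stripped; internal '*' is not a valid protein residue here.
        if residues.endswith("*"):
            residues = residues[:-1]
        if not residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        for pos, ch in enumerate(residues, start=1):
            if ch not in PROTEIN_ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CdsRecord:
    """A coding nucleotide span; ``N`` marks assembly-gap bases."""

    id: str
    bases: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        bases = self.bases.upper()
        for pos, ch in enumerate(bases, start=1):
            if ch not in NUCLEOTIDE_ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0, 1 or 2")
        if len(bases) - self.frame_offset < 3:
            raise ValueError(
                f"record {self.id!r}: fewer than one codon after frame offset"
            )
        object.__setattr__(self, "bases", bases)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class DefectFlags:
    """Structural defects detectable from a CDS span alone."""

    missing_start: bool = False
    missing_stop: bool = False
    premature_stop: bool = False
    frameshift: bool = False

    def any(self) -> bool:
        return self.missing_start or self.missing_stop or self.premature_stop or self.frameshift


def _parse_header(header: str) -> tuple[str, str, GeneLabel]:
    """Split an ``id|SPECIES|GENE`` header; missing tokens default."""
    tokens = header.split("|")
    rec_id = tokens[0].strip()
    species = tokens[1].strip().upper() if len(tokens) > 1 else ""
    gene = GeneLabel.from_token(tokens[2].strip()) if len(tokens) > 2 else GeneLabel.OTHER
    return rec_id, species, gene


def read_fasta(
    path: Union[str, Path], kind: str = "protein"
) -> list[ProteinRecord] | list[CdsRecord]:
    """Read a FASTA file into protein or CDS records.

    Parameters
    ----------
    path:
        FASTA file.  Headers follow the ``id|SPECIES|GENE`` dialect; the
        species and gene tokens are optional.
    kind:
        ``"protein"`` or ``"nucleotide"``.

    Raises
    ------
    ValueError
        On an empty file, duplicate ids, or characters outside the declared
        alphabet (the error names the offending id and position).
    """
    if kind not in ("protein", "nucleotide"):
        raise ValueError(f"unknown kind {kind!r}")
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise ValueError(f"no records in {path}")
    records: list = []
    seen: set[str] = set()
    for entry in entries:
        rec_id, species, gene = _parse_header(entry.description)
        if rec_id in seen:
            raise ValueError(f"duplicate id {rec_id!r} in {path}")
        seen.add(rec_id)
        seq = str(entry.seq).upper()
        if kind == "protein":
            records.append(
                ProteinRecord(id=rec_id, residues=seq, species_code=species, gene_label=gene)
            )
        else:
            records.append(CdsRecord(id=rec_id, bases=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord | CdsRecord], path: Union[str, Path]) -> None:
    """Write records back out in the ``id|SPECIES|GENE`` header dialect."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, ProteinRecord):
                header = f"{rec.id}|{rec.species_code}|{rec.gene_label.value}"
                seq = rec.residues
            else:
                header = rec.id
                seq = rec.bases
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def translate_cds(cds: CdsRecord) -> tuple[str, DefectFlags]:
    """Translate a CDS under the standard code with gap-aware rules.

    Any codon containing at least one ``N`` translates to ``X``.  A trailing
    incomplete codon is ignored.  The returned string keeps internal stop
    codons as ``*`` but drops a terminal stop.

    Flags: ``missing_start`` (first codon is not ATG), ``missing_stop`` (last
    complete codon is not a stop), ``premature_stop`` (a stop occurs before
    the last complete codon), ``frameshift`` (span length after the frame
    offset is not a multiple of 3).
    """
    span = cds.bases[cds.frame_offset :]
    n_codons = len(span) // 3
    if n_codons < 1:
        raise ValueError(f"record {cds.id!r}: shorter than one codon")
    codons = [span[3 * i : 3 * i + 3] for i in range(n_codons)]
    residues = []
    premature = False
    for i, codon in enumerate(codons):
        if "N" in codon:
            residues.append("X")
            continue
        aa = _CODON_TABLE[codon]
        if aa == "*" and i < n_codons - 1:
            premature = True
        residues.append(aa)
    protein = "".join(residues)
    if protein.endswith("*"):
        protein = protein[:-1]
    flags = DefectFlags(
        missing_start=codons[0] != "ATG",
        missing_stop=codons[-1] not in STOP_CODONS,
        premature_stop=premature,
        frameshift=(len(cds.bases) - cds.frame_offset) % 3 != 0,
    )
    return protein, flags


# Fields rendered with the fixed 2-decimal convention used in loop reports.
_TWO_DP_FIELDS = {"mean_size", "gs_fraction", "central_unknown_fraction"}


def _render(name: str, value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, Enum):
        return str(value.value)
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, float):
        if name in _TWO_DP_FIELDS:
            return f"{value:.2f}"
        return repr(value)
    return str(value)


def write_table(rows: Sequence, path: Union[str, Path], columns: Sequence[str] | None = None) -> None:
    """Write flat records (dataclasses or dicts) as a headered TSV.

    Column order follows field declaration order of the first row; all rows
    must share the same field set.  Selected float fields are rendered with
    two decimals.  ``columns`` supplies the header for an empty row list.
    """
    rows = list(rows)
    with open(path, "w") as fh:
        if not rows:
            fh.write(("\t".join(columns) if columns else "") + "\n")
            return
        first = rows[0]
        if is_dataclass(first):
            names = [f.name for f in dc_fields(first)]
            dicts = [asdict(r) if is_dataclass(r) else None for r in rows]
            if any(d is None for d in dicts):
                raise ValueError("heterogeneous rows: mix of dataclasses and other types")
        else:
            names = list(first.keys())
            dicts = [dict(r) for r in rows]
        for d in dicts:
            if list(d.keys()) != names and set(d.keys()) != set(names):
                raise ValueError("heterogeneous rows: field sets differ")
        fh.write("\t".join(names) + "\n")
        for d in dicts:
            fh.write("\t".join(_render(n, d[n]) for n in names) + "\n")


def log(message: str, quiet: bool = False) -> None:
    if not quiet:
        print(message, file=sys.stderr)
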