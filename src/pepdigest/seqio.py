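"""Reading protein FASTA/FASTQ and writing digestion results.

Input format is auto-detected from the first non-blank character ('>' for
FASTA, '@' for FASTQ); records are streamed so memory stays bounded by the
largest single sequence, not the file.  FASTQ quality strings are parsed
and discarded.  Results are written as multi-FASTA, CSV or TSV; the FASTA
header dialect is ``>parent_ordinal_enzyme_position_length_mass_pI``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .alphabet import normalize
from .digest import Peptide

OUTPUT_FORMATS = ("fasta", "csv", "tsv")

CSV_COLUMNS = (
    "parent_id",
    "enzyme",
    "ordinal",
    "cleavage_position",
    "length",
    "mass",
    "pI",
    "sequence",
)


@dataclass(frozen=True)
class SequenceRecord:
    """One input protein: header token, remaining description, residues."""

    id: str
    description: str
    sequence: str


class FormatError(ValueError):
    """Malformed or unrecognized sequence file."""


def _make_record(title: str, seq: str) -> SequenceRecord:
    title = title.strip()
    if not title:
        raise FormatError("record with empty header")
    ident, _, desc = title.partition(" ")
    if not seq:
        raise FormatError(f"record '{ident}' has an empty sequence")
    return SequenceRecord(ident, desc.strip(), normalize(seq, record_id=ident))


def read_records(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records from a (multi-)FASTA or FASTQ protein file."""
    path = Path(path)
    with path.open() as handle:
        first = handle.read(1)
        while first.isspace() and first:
            first = handle.read(1)
        handle.seek(0)
        if first == ">":
            parser: Iterable = SimpleFastaParser(handle)
            for title, seq in parser:
                yield _make_record(title, seq)
        elif first == "@":
            for title, seq, _qual in FastqGeneralIterator(handle):
                yield _make_record(title, seq)
        elif first == "":
            raise FormatError(f"{path}: empty input file")
        else:
            raise FormatError(
                f"{path}: unrecognized format (expected '>' or '@', got {first!r})"
            )


def format_mass(mass: float) -> str:
    return f"{mass:.4f}"


def format_pi(pi: float) -> str:
    return f"{pi:.2f}"


def fasta_header(pep: Peptide) -> str:
    return "_".join(
        (
            pep.parent_id,
            str(pep.ordinal),
            pep.enzyme_name,
            str(pep.cleavage_position),
            str(pep.length),
            format_mass(pep.mass),
            format_pi(pep.pI),
        )
    )


def write_results(
    peptides: Iterable[Peptide], fmt: str, dest: IO[str], header: bool = True
) -> int:
    """Write peptides to an open text handle; returns the peptide count.

    ``header`` controls the csv/tsv header row so callers streaming one
    record at a time can emit it exactly once.
    """
    if fmt not in OUTPUT_FORMATS:
        raise ValueError(
            f"unknown output format {fmt!r}; expected one of {OUTPUT_FORMATS}"
        )
    count = 0
    if fmt == "fasta":
        for pep in peptides:
            dest.write(f">{fasta_header(pep)}\n{pep.sequence.upper()}\n")
            count += 1
        return count
    writer = csv.writer(dest, delimiter="," if fmt == "csv" else "\t", lineterminator="\n")
    if header:
        writer.writerow(CSV_COLUMNS)
    for pep in peptides:
        writer.writerow(
            (
                pep.parent_id,
                pep.enzyme_name,
                pep.ordinal,
                pep.cleavage_position,
                pep.length,
                format_mass(pep.mass),
                format_pi(pep.pI),
                pep.sequence.upper(),
            )
        )
        count += 1
    return count
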