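"""Genome FASTA input/output and genome-length accounting.

Coordinates throughout the package are 0-based, half-open ``[start, end)``.
The genome length used as the coverage denominator defaults to every letter
of the assembly including N (the "reported sequence length"); ``acgt_only``
excludes ambiguity codes for gap-heavy assemblies.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class GenomeRecord:
    """One FASTA record (chromosome/scaffold): header token + sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Genome:
    """An ordered collection of records, e.g. one species assembly."""

    records: tuple[GenomeRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in genome")
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    def __iter__(self) -> Iterator[GenomeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, record_id: str) -> GenomeRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)


def _open_text(path: Path) -> IO[str]:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_genome(path: str | Path) -> Genome:
    """Read a (possibly gzipped) FASTA file; sequences are uppercased.

    Record order is preserved.  Raises ``ValueError`` for empty or
    non-FASTA input.
    """
    path = Path(path)
    with _open_text(path) as fh:
        head = fh.read(1)
        if head == "":
            raise ValueError(f"{path}: empty file")
        if head != ">":
            raise ValueError(f"{path}: not FASTA (first byte is {head!r}, expected '>')")
        fh.seek(0)
        records = tuple(
            GenomeRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return Genome(records)


def write_genome(genome: Genome, path: str | Path, line_width: int = 70) -> None:
    """Write a genome to plain FASTA (gzip if the path ends in .gz)."""
    path = Path(path)
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in genome]
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            SeqIO.write(seq_records, fh, "fasta")
    else:
        SeqIO.write(seq_records, str(path), "fasta")


def genome_length(genome: Genome, denominator_mode: str = "all_bases") -> int:
    """Total genome length in bp under the chosen accounting.

    ``all_bases`` counts every letter (the reported assembly length, the
    default IgC denominator); ``acgt_only`` counts unambiguous bases only.
    """
    if denominator_mode == "all_bases":
        return genome.total_length
    if denominator_mode == "acgt_only":
        return sum(1 for r in genome for c in r.sequence if c in _ACGT)
    raise ValueError(
        f"denominator_mode must be 'all_bases' or 'acgt_only', got {denominator_mode!r}"
    )
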