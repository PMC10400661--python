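"""FASTA/FASTQ I/O helpers (Biopython-backed, gzip-aware)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "read_fasta",
    "read_fasta_lineages",
    "write_fasta",
    "read_fastq",
    "write_fastq",
]


def _open(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records (wrapped lines fine) as (full header, sequence)."""
    with _open(path) as fh:
        return [(title, seq.upper()) for title, seq in SimpleFastaParser(fh)]


def read_fasta_lineages(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTA with SILVA-style headers: ``>ID lineage;by;semicolons``.

    Returns (id, lineage, sequence); the lineage is empty if the header has
    no description.
    """
    out = []
    for title, seq in read_fasta(path):
        parts = title.split(None, 1)
        rec_id = parts[0]
        lineage = parts[1].strip() if len(parts) > 1 else ""
        out.append((rec_id, lineage, seq))
    return out


def write_fasta(
    path: str | Path, records: Iterable[tuple[str, str]], width: int = 70
) -> None:
    with _open(path, "wt") as fh:
        for title, seq in records:
            fh.write(f">{title}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTQ (optionally gzip) as (title, sequence, quality)."""
    with _open(path) as fh:
        return list(FastqGeneralIterator(fh))


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with _open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    with _open(path, "wt") as fh:
        for title, seq, qual in reads:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
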