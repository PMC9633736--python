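"""FASTA/FASTQ plumbing and whole-file reduction helpers."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import PositionMap, ReductionFunction, apply_reduction

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_sequences",
    "reduce_fasta",
    "reduce_read",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences by record id, uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
            if not seq:
                fh.write("\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """(name, sequence, quality) triples; qualities kept verbatim."""
    with open(path) as fh:
        return [(title.split()[0], seq, qual) for title, seq, qual in FastqGeneralIterator(fh)]


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_sequences(path: str | Path) -> list[tuple[str, str, str | None]]:
    """Read FASTA or FASTQ (sniffed from the first byte) as (name, seq, qual)."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return [(n, s, q) for n, s, q in read_fastq(path)]
    return [(n, s, None) for n, s in read_fasta(path).items()]


def reduce_fasta(
    f: ReductionFunction, seqs: Mapping[str, str]
) -> tuple[dict[str, str], dict[str, PositionMap]]:
    """Reduce every sequence, returning reduced sequences and position maps."""
    reduced: dict[str, str] = {}
    posmaps: dict[str, PositionMap] = {}
    for name, seq in seqs.items():
        reduced[name], posmaps[name] = apply_reduction(f, seq)
    return reduced, posmaps


def reduce_read(
    f: ReductionFunction, name: str, seq: str, qual: str | None = None
) -> tuple[str, str, str | None]:
    """Reduce one read; the quality string is subset to the emitted positions."""
    out, pm = apply_reduction(f, seq)
    if qual is None:
        return name, out, None
    return name, out, "".join(qual[i] for i in pm.anchors)
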