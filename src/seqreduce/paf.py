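"""Minimal PAF (pairwise alignment format) records and I/O.

Only the 12 mandatory columns plus the ``tp:A:`` type tag are
interpreted; other tags are carried through verbatim.  Records lacking a
``tp:A:`` tag are treated as primary alignments.  Coordinates are 0-based
half-open, as in the format itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

__all__ = ["MappingRecord", "parse_paf", "read_paf", "write_paf"]


@dataclass(frozen=True)
class MappingRecord:
    """One PAF alignment line."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alnlen: int
    mapq: int
    primary: bool = True
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"mapq must be in 0..60, got {self.mapq}")
        if self.qstart > self.qend or self.tstart > self.tend:
            raise ValueError("interval start must not exceed end")

    def to_line(self) -> str:
        fields = [
            self.qname, str(self.qlen), str(self.qstart), str(self.qend),
            self.strand,
            self.tname, str(self.tlen), str(self.tstart), str(self.tend),
            str(self.nmatch), str(self.alnlen), str(self.mapq),
            f"tp:A:{'P' if self.primary else 'S'}",
        ]
        fields.extend(t for t in self.tags if not t.startswith("tp:A:"))
        return "\t".join(fields)


def parse_paf(lines: Iterable[str]) -> Iterator[MappingRecord]:
    """Parse PAF lines into :class:`MappingRecord` objects."""
    for idx, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(f"PAF line {idx}: expected >= 12 columns, got {len(fields)}")
        tags = tuple(fields[12:])
        primary = True
        for tag in tags:
            if tag.startswith("tp:A:"):
                primary = tag[5:] == "P"
                break
        yield MappingRecord(
            qname=fields[0], qlen=int(fields[1]),
            qstart=int(fields[2]), qend=int(fields[3]),
            strand=fields[4],
            tname=fields[5], tlen=int(fields[6]),
            tstart=int(fields[7]), tend=int(fields[8]),
            nmatch=int(fields[9]), alnlen=int(fields[10]), mapq=int(fields[11]),
            primary=primary, tags=tags,
        )


def read_paf(path: str | Path) -> list[MappingRecord]:
    with open(path) as fh:
        return list(parse_paf(fh))


def write_paf(records: Iterable[MappingRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")
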