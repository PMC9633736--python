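"""Lift-over between original and reduced coordinate systems.

A reduction deletes characters, so a reduced sequence index corresponds
to exactly one original index (its anchor), while an original index may
have no reduced image.  Interval translation onto the reduced sequence
rounds *inward*: the translated interval covers exactly the reduced
positions whose anchors fall inside the original interval, so a
translated truth interval is always contained in the image of the true
interval (conservative for the overlap-based correctness test).
Reductions are applied to the forward strand only, so lift-over never
reverse-complements coordinates; strand is carried through untouched.

All coordinates are 0-based half-open, as in PAF and BED.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from .core import PositionMap
from .paf import MappingRecord

__all__ = [
    "GenomicInterval",
    "original_to_reduced",
    "reduced_to_original",
    "translate_paf",
    "read_bed",
    "write_bed",
    "write_posmaps",
    "read_posmaps",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded 0-based half-open interval on a named sequence."""

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start <= self.end:
            raise ValueError(f"require 0 <= start <= end, got [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of the intersection; 0 when the names differ."""
        if self.name != other.name:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def original_to_reduced(pm: PositionMap, iv: GenomicInterval) -> GenomicInterval:
    """Translate an original-coordinate interval onto the reduced sequence.

    The result spans the reduced positions whose anchors lie in
    ``[start, end)``; it is empty when the interval covers only deleted
    positions.
    """
    if not 0 <= iv.start <= iv.end <= pm.original_length:
        raise ValueError(
            f"interval [{iv.start}, {iv.end}) outside [0, {pm.original_length}]"
        )
    start = int(np.searchsorted(pm.anchors, iv.start, side="left"))
    end = int(np.searchsorted(pm.anchors, iv.end, side="left"))
    return replace(iv, start=start, end=max(start, end))


def reduced_to_original(pm: PositionMap, iv: GenomicInterval) -> GenomicInterval:
    """Translate a reduced-coordinate interval back to original coordinates.

    Start maps to its anchor and the end to one past the anchor of the
    last covered reduced position; an empty interval stays empty (placed
    at its start's anchor).
    """
    n = pm.reduced_length
    if not 0 <= iv.start <= iv.end <= n:
        raise ValueError(f"interval [{iv.start}, {iv.end}) outside [0, {n}]")
    if iv.start == iv.end:
        pos = pm.anchor(iv.start) if iv.start < n else pm.original_length
        return replace(iv, start=pos, end=pos)
    return replace(iv, start=pm.anchor(iv.start), end=pm.anchor(iv.end - 1) + 1)


def translate_paf(
    records: Iterable[MappingRecord],
    posmaps: Mapping[str, PositionMap],
    direction: str = "to_original",
    primary_only: bool = False,
) -> Iterator[MappingRecord]:
    """Translate the target coordinates of PAF records between spaces.

    ``direction`` is ``"to_original"`` (the pipeline direction: mappings
    on a reduced reference lifted back) or ``"to_reduced"``.  Read name,
    strand and mapq pass through untouched; the target length is restated
    in the destination coordinate space.  With ``primary_only``,
    records flagged secondary are dropped.
    """
    if direction not in ("to_original", "to_reduced"):
        raise ValueError(f"direction must be to_original or to_reduced, got {direction!r}")
    translate = reduced_to_original if direction == "to_original" else original_to_reduced
    for rec in records:
        if primary_only and not rec.primary:
            continue
        pm = posmaps.get(rec.tname)
        if pm is None:
            raise ValueError(f"no position map for target {rec.tname!r}")
        iv = translate(pm, GenomicInterval(rec.tname, rec.tstart, rec.tend, rec.strand))
        tlen = pm.original_length if direction == "to_original" else pm.reduced_length
        yield replace(rec, tstart=iv.start, tend=iv.end, tlen=tlen)


# ---------------------------------------------------------------------------
# BED 3+ I/O (name, start, end[, extra columns ignored on read]).

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    for idx, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path} line {idx}: BED needs >= 3 columns")
        strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
        out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.name}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Position-map sidecar TSV: one run-length-encoded row per contiguous run
# of consecutive anchors, so maps are not recomputed per pipeline stage.

def write_posmaps(posmaps: Mapping[str, PositionMap], path: str | Path) -> None:
    """Columns: target, reduced_start, original_start, run_length."""
    with open(path, "w") as fh:
        fh.write("#target\treduced_start\toriginal_start\tlength\n")
        for target in posmaps:
            pm = posmaps[target]
            fh.write(f"##{target}\toriginal_length={pm.original_length}\n")
            a = pm.anchors
            if a.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(a) != 1) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [a.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{target}\t{s}\t{a[s]}\t{e - s}\n")


def read_posmaps(path: str | Path) -> dict[str, PositionMap]:
    lengths: dict[str, int] = {}
    runs: dict[str, list[np.ndarray]] = {}
    for idx, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("##"):
            target, meta = line[2:].split("\t")
            lengths[target] = int(meta.split("=", 1)[1])
            runs.setdefault(target, [])
            continue
        if not line or line.startswith("#"):
            continue
        target, _rstart, ostart, length = line.split("\t")
        if target not in lengths:
            raise ValueError(f"{path} line {idx}: run for undeclared target {target!r}")
        runs[target].append(np.arange(int(ostart), int(ostart) + int(length), dtype=np.int64))
    return {
        t: PositionMap(
            np.concatenate(r) if r else np.empty(0, dtype=np.int64), lengths[t]
        )
        for t, r in runs.items()
    }
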