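"""Mapping evaluation and MSR selection.

Implements the mapeval-style correctness criterion (a read is correctly
placed when the intersection of its true origin interval and its mapped
interval is at least 10% of their union), cumulative mapq-threshold
curves of (fraction of reads mapped, mapping error rate), and the
three-list selection procedure that promotes streaming sequence
reductions to *mapping-friendly* status relative to a homopolymer
compression reference point.

A curve point at threshold ``t`` aggregates the primary alignments with
``mapq >= t``: the fraction mapped is relative to all simulated reads
(reads whose reduced form is empty can never be mapped but stay in the
denominator), and the error rate is the fraction of those alignments that
fail the correctness criterion (defined as 0 when nothing is mapped).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coordinates import GenomicInterval
from .paf import MappingRecord

__all__ = [
    "ReadTruth",
    "EvalPoint",
    "EvalCurve",
    "MIN_OVERLAP_FRACTION",
    "FIGURE_THRESHOLDS",
    "FULL_THRESHOLDS",
    "is_correct",
    "eval_curve",
    "respective_threshold",
    "percent_better",
    "select_msrs",
    "SelectionReport",
    "repeat_read_filter",
    "truth_from_name",
    "read_truth_tsv",
    "write_truth_tsv",
    "read_curve_tsv",
    "write_curve_tsv",
]

#: mapeval correctness: |intersection| / |union| of truth and mapped interval.
MIN_OVERLAP_FRACTION = 0.10

#: The seven thresholds plotted on published curves, highest first.
FIGURE_THRESHOLDS: tuple[int, ...] = (60, 50, 40, 30, 20, 10, 0)

#: Every integer threshold, for respective-threshold scans.
FULL_THRESHOLDS: tuple[int, ...] = tuple(range(60, -1, -1))


@dataclass(frozen=True)
class ReadTruth:
    """A simulated read's name and its true interval of origin."""

    name: str
    origin: GenomicInterval


@dataclass(frozen=True)
class EvalPoint:
    threshold: int
    fraction_mapped: float
    error_rate: float
    n_mapped: int
    n_errors: int


@dataclass(frozen=True)
class EvalCurve:
    """Cumulative (fraction mapped, error rate) per mapq threshold.

    Points are ordered by strictly decreasing threshold, the convention
    of the published curves (60 down to 0, left to right).
    """

    points: tuple[EvalPoint, ...]
    total_reads: int

    def __post_init__(self) -> None:
        ts = [p.threshold for p in self.points]
        if any(later >= earlier for later, earlier in zip(ts[1:], ts)):
            raise ValueError("thresholds must be strictly decreasing")
        for p in self.points:
            if not (0 <= p.fraction_mapped <= 1 and 0 <= p.error_rate <= 1):
                raise ValueError("fraction and error rate must lie in [0, 1]")

    def point_at(self, t: int) -> EvalPoint:
        for p in self.points:
            if p.threshold == t:
                return p
        raise KeyError(f"curve has no point at threshold {t}")

    def fraction_at(self, t: int) -> float:
        return self.point_at(t).fraction_mapped

    def error_at(self, t: int) -> float:
        return self.point_at(t).error_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": [p.threshold for p in self.points],
                "mapped": [p.n_mapped for p in self.points],
                "fraction_mapped": [p.fraction_mapped for p in self.points],
                "errors": [p.n_errors for p in self.points],
                "error_rate": [p.error_rate for p in self.points],
            }
        )


def is_correct(m: MappingRecord, truth: ReadTruth) -> bool:
    """mapeval correctness: intersection >= 10% of the union.

    Both intervals must be in the same coordinate space.  A mapping to a
    different target sequence is always incorrect.
    """
    mapped = GenomicInterval(m.tname, m.tstart, m.tend)
    if mapped.name != truth.origin.name:
        return False
    inter = mapped.overlap(truth.origin)
    union = mapped.length + truth.origin.length - inter
    if union == 0:
        # two empty intervals: degenerate, count as incorrect
        return False
    return inter / union >= MIN_OVERLAP_FRACTION


def eval_curve(
    mappings: Iterable[MappingRecord],
    truths: Iterable[ReadTruth] | Mapping[str, ReadTruth],
    thresholds: Sequence[int] = FIGURE_THRESHOLDS,
) -> EvalCurve:
    """Build the mapq-threshold curve for one read set and mapping run.

    Only primary alignments contribute (one per read; the first primary
    record seen for a read name wins).  A mapping whose read name has no
    truth entry is an error, as it indicates mismatched inputs.
    """
    if isinstance(truths, Mapping):
        truth_by_name = dict(truths)
    else:
        truth_by_name = {t.name: t for t in truths}
    total = len(truth_by_name)

    seen: dict[str, tuple[int, bool]] = {}
    for rec in mappings:
        if not rec.primary:
            continue
        if rec.qname not in truth_by_name:
            raise ValueError(f"mapping for unknown read {rec.qname!r}")
        if rec.qname not in seen:
            seen[rec.qname] = (rec.mapq, is_correct(rec, truth_by_name[rec.qname]))

    mapq = np.array([v[0] for v in seen.values()], dtype=np.int64)
    wrong = np.array([not v[1] for v in seen.values()], dtype=bool)

    points = []
    for t in sorted(set(thresholds), reverse=True):
        sel = mapq >= t
        n_mapped = int(sel.sum())
        n_errors = int(wrong[sel].sum())
        points.append(
            EvalPoint(
                threshold=int(t),
                fraction_mapped=n_mapped / total if total else 0.0,
                error_rate=n_errors / n_mapped if n_mapped else 0.0,
                n_mapped=n_mapped,
                n_errors=n_errors,
            )
        )
    return EvalCurve(points=tuple(points), total_reads=total)


def respective_threshold(
    curve: EvalCurve, ref_fraction: float, ref_error: float
) -> int | None:
    """Highest threshold at which the curve strictly beats the reference.

    Strictly higher fraction mapped AND strictly lower error rate than
    the reference point (HPC at mapq 60 in the published procedure);
    ``None`` when no threshold qualifies, meaning the reduction is
    discarded from further consideration.
    """
    for p in curve.points:  # ordered high threshold first
        if p.fraction_mapped > ref_fraction and p.error_rate < ref_error:
            return p.threshold
    return None


def percent_better(curve: EvalCurve, ref_fraction: float, ref_error: float) -> float:
    """Fraction of the 60 thresholds 1..60 strictly beating the reference."""
    better = 0
    for t in range(1, 61):
        p = curve.point_at(t)
        if p.fraction_mapped > ref_fraction and p.error_rate < ref_error:
            better += 1
    return better / 60


@dataclass(frozen=True)
class SelectionReport:
    """Outcome of the three-list MSR selection."""

    ref_fraction: float
    ref_error: float
    respective_thresholds: dict[str, int | None]
    top_fraction: tuple[str, ...]
    top_error: tuple[str, ...]
    top_percent: tuple[str, ...]
    union: tuple[str, ...]
    best_fraction: str | None  # MSR_F analog
    best_error: str | None     # MSR_E analog
    best_percent: str | None   # MSR_P analog
    percent_better: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ssr in self.union:
            rows.append(
                {
                    "ssr": ssr,
                    "respective_threshold": self.respective_thresholds.get(ssr),
                    "percent_better": self.percent_better.get(ssr, 0.0),
                    "in_top_fraction": ssr in self.top_fraction,
                    "in_top_error": ssr in self.top_error,
                    "in_top_percent": ssr in self.top_percent,
                    "best_in_category": "|".join(
                        tag
                        for tag, best in (
                            ("fraction", self.best_fraction),
                            ("error", self.best_error),
                            ("percent", self.best_percent),
                        )
                        if best == ssr
                    ),
                }
            )
        return pd.DataFrame(rows)


def select_msrs(
    curves: Mapping[str, EvalCurve],
    hpc_curve: EvalCurve,
    top_n: int = 20,
) -> SelectionReport:
    """Select promising reductions against the HPC mapq-60 reference point.

    Three ranked lists of ``top_n`` entries each: highest fraction mapped
    at the respective threshold, lowest error rate at the respective
    threshold, and highest percentage of thresholds strictly better than
    the reference.  Reductions with no respective threshold are discarded
    from the first two lists; a zero percent-better score excludes a
    reduction from the third.  Ties break by (metric, then id) so the
    output is reproducible.  The report also flags the three
    best-in-category reductions among the union: highest fraction mapped
    at threshold 0, lowest error at the respective threshold, and highest
    percent-better.
    """
    ref_fraction = hpc_curve.fraction_at(60)
    ref_error = hpc_curve.error_at(60)

    rts: dict[str, int | None] = {}
    pbs: dict[str, float] = {}
    qualified: list[str] = []
    for ssr_id in sorted(curves):
        curve = curves[ssr_id]
        rt = respective_threshold(curve, ref_fraction, ref_error)
        rts[ssr_id] = rt
        pbs[ssr_id] = percent_better(curve, ref_fraction, ref_error)
        if rt is not None:
            qualified.append(ssr_id)

    def frac_at_rt(ssr_id: str) -> float:
        return curves[ssr_id].fraction_at(rts[ssr_id])

    def err_at_rt(ssr_id: str) -> float:
        return curves[ssr_id].error_at(rts[ssr_id])

    top_fraction = tuple(
        sorted(qualified, key=lambda s: (-frac_at_rt(s), s))[:top_n]
    )
    top_error = tuple(sorted(qualified, key=lambda s: (err_at_rt(s), s))[:top_n])
    scored = [s for s in sorted(curves) if pbs[s] > 0]
    top_percent = tuple(sorted(scored, key=lambda s: (-pbs[s], s))[:top_n])

    union = tuple(sorted(set(top_fraction) | set(top_error) | set(top_percent)))

    best_fraction = min(
        union, key=lambda s: (-curves[s].fraction_at(0), s), default=None
    )
    in_union_qualified = [s for s in union if rts[s] is not None]
    best_error = min(in_union_qualified, key=lambda s: (err_at_rt(s), s), default=None)
    best_percent = min(union, key=lambda s: (-pbs[s], s), default=None)

    return SelectionReport(
        ref_fraction=ref_fraction,
        ref_error=ref_error,
        respective_thresholds=rts,
        top_fraction=top_fraction,
        top_error=top_error,
        top_percent=top_percent,
        union=union,
        best_fraction=best_fraction,
        best_error=best_error,
        best_percent=best_percent,
        percent_better=pbs,
    )


def repeat_read_filter(
    truths: Iterable[ReadTruth], repeats: Iterable[GenomicInterval]
) -> list[ReadTruth]:
    """Keep reads originating mostly from repeat regions.

    A read passes when the total overlap of its origin with the (merged)
    repeat intervals exceeds half the read's origin length.
    """
    merged: dict[str, list[tuple[int, int]]] = {}
    for iv in repeats:
        merged.setdefault(iv.name, []).append((iv.start, iv.end))
    for name, ivs in merged.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[name] = out

    kept = []
    for truth in truths:
        o = truth.origin
        cover = sum(
            max(0, min(e, o.end) - max(s, o.start))
            for s, e in merged.get(o.name, [])
        )
        if o.length > 0 and cover > 0.5 * o.length:
            kept.append(truth)
    return kept


# ---------------------------------------------------------------------------
# Truth I/O: TSV (read, target, start, end, strand) or encoded read names.

def truth_from_name(name: str) -> ReadTruth:
    """Decode a ``{id}!{target}!{start}!{end}!{strand}`` read name."""
    parts = name.split("!")
    if len(parts) != 5:
        raise ValueError(f"read name {name!r} does not encode a truth interval")
    _, target, start, end, strand = parts
    return ReadTruth(name, GenomicInterval(target, int(start), int(end), strand))


def read_truth_tsv(path: str | Path) -> list[ReadTruth]:
    truths = []
    for idx, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("read\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"{path} line {idx}: expected 5 columns")
        name, target, start, end, strand = fields
        truths.append(ReadTruth(name, GenomicInterval(target, int(start), int(end), strand)))
    return truths


def write_truth_tsv(truths: Iterable[ReadTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read\ttarget\tstart\tend\tstrand\n")
        for t in truths:
            o = t.origin
            fh.write(f"{t.name}\t{o.name}\t{o.start}\t{o.end}\t{o.strand}\n")


def write_curve_tsv(curve: EvalCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#total_reads={curve.total_reads}\n")
        curve.to_frame().to_csv(fh, sep="\t", index=False)


def read_curve_tsv(path: str | Path) -> EvalCurve:
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("#total_reads="):
        raise ValueError(f"{path}: missing #total_reads header")
    total = int(text[0].split("=", 1)[1])
    header = text[1].split("\t")
    points = []
    for line in text[2:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        points.append(
            EvalPoint(
                threshold=int(row["threshold"]),
                fraction_mapped=float(row["fraction_mapped"]),
                error_rate=float(row["error_rate"]),
                n_mapped=int(row["mapped"]),
                n_errors=int(row["errors"]),
            )
        )
    return EvalCurve(points=tuple(points), total_reads=total)
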