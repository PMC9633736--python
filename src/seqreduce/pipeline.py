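"""The end-to-end pipeline: reduce -> map -> translate -> evaluate -> select.

For each requested reduction the reference and the reads are transformed,
the reduced reads are mapped to the reduced reference (by an external
mapper command template when one is configured, otherwise by the
synthetic mapping generator so the pipeline runs without any binaries),
truth intervals are translated into reduced coordinates, primary
alignments are scored with the mapeval criterion, and per-threshold
curves plus a selection report are written under a single run directory
with a manifest.
"""

from __future__ import annotations

import json
import shlex
import subprocess
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .coordinates import original_to_reduced, read_bed, write_posmaps
from .evaluation import (
    FIGURE_THRESHOLDS,
    FULL_THRESHOLDS,
    EvalCurve,
    ReadTruth,
    eval_curve,
    read_truth_tsv,
    select_msrs,
    truth_from_name,
    write_curve_tsv,
    write_truth_tsv,
)
from .io import read_fasta, read_sequences, reduce_fasta, reduce_read, write_fasta, write_fastq
from .named import resolve_reduction
from .paf import read_paf, write_paf
from .simdata import synth_mappings

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_MAPPER_TEMPLATE"]

#: Recorded default external-mapper invocation (map-ont preset, base-level
#: alignment); used only when `mapper_template` is set to "default".
DEFAULT_MAPPER_TEMPLATE = "minimap2 -x map-ont -c -o {paf} {ref} {reads}"


@dataclass(frozen=True)
class PipelineConfig:
    """One evaluation run over a fixed read set and reference."""

    reference: str
    reads: str
    outdir: str
    ssrs: Sequence[str] = ("raw", "hpc")
    truth: str | None = None  # TSV; None decodes truth from read names
    repeats: str | None = None  # optional BED, recorded in the manifest
    mapper_template: str | None = None  # e.g. DEFAULT_MAPPER_TEMPLATE
    wrong_rate: float = 0.05  # synthetic-mapping knobs, used without a mapper
    mapq_model: str = "informative"
    thresholds: Sequence[int] = FIGURE_THRESHOLDS
    seed: int = 0
    reference_ssr: str = "hpc"  # selection reference curve, if present

    def validate(self) -> None:
        for attr in ("reference", "reads"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr} path does not exist: {p}")
        if self.truth and not Path(self.truth).exists():
            raise FileNotFoundError(f"truth path does not exist: {self.truth}")
        if self.repeats and not Path(self.repeats).exists():
            raise FileNotFoundError(f"repeats path does not exist: {self.repeats}")
        if not self.ssrs:
            raise ValueError("at least one reduction must be requested")


def _safe_name(ssr: str) -> str:
    return Path(ssr).stem.replace("/", "_") or "ssr"


def run_pipeline(cfg: PipelineConfig) -> dict[str, EvalCurve]:
    """Run the full pipeline; returns the full-resolution curves by SSR id.

    File outputs per reduction land in ``outdir/<ssr>/``: reduced
    reference, reduced reads, position-map sidecar, PAF, and curve TSV.
    A selection report is written when the configured reference reduction
    (HPC by default) is among the runs.  Mapper invocation failures are
    recorded in the manifest and do not abort the remaining reductions.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reference = read_fasta(cfg.reference)
    reads = read_sequences(cfg.reads)
    if cfg.truth:
        truths = read_truth_tsv(cfg.truth)
    else:
        truths = [truth_from_name(name) for name, _s, _q in reads]

    curves: dict[str, EvalCurve] = {}
    errors: dict[str, str] = {}
    for ssr in cfg.ssrs:
        ssr_id = _safe_name(ssr)
        func = resolve_reduction(ssr)
        d = outdir / ssr_id
        d.mkdir(parents=True, exist_ok=True)

        red_ref, posmaps = reduce_fasta(func, reference)
        write_fasta(red_ref, d / "reduced_ref.fa")
        write_posmaps(posmaps, d / "posmap.tsv")
        red_reads = [reduce_read(func, n, s, q or "I" * len(s)) for n, s, q in reads]
        write_fastq(red_reads, d / "reduced_reads.fq")

        red_truths = [
            ReadTruth(t.name, original_to_reduced(posmaps[t.origin.name], t.origin))
            for t in truths
        ]
        write_truth_tsv(red_truths, d / "truth_reduced.tsv")

        paf_path = d / "mappings.paf"
        if cfg.mapper_template:
            template = (
                DEFAULT_MAPPER_TEMPLATE
                if cfg.mapper_template == "default"
                else cfg.mapper_template
            )
            cmd = template.format(
                ref=shlex.quote(str(d / "reduced_ref.fa")),
                reads=shlex.quote(str(d / "reduced_reads.fq")),
                paf=shlex.quote(str(paf_path)),
            )
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0 or not paf_path.exists():
                errors[ssr_id] = f"mapper failed (exit {proc.returncode}): {proc.stderr[-500:]}"
                print(f"[seqreduce] {errors[ssr_id]}", file=sys.stderr)
                continue
            records = read_paf(paf_path)
        else:
            lengths = {name: len(seq) for name, seq in red_ref.items()}
            records = synth_mappings(
                red_truths, lengths, cfg.wrong_rate, cfg.mapq_model, cfg.seed
            )
            write_paf(records, paf_path)

        primary = [r for r in records if r.primary]
        curve = eval_curve(primary, red_truths, FULL_THRESHOLDS)
        curves[ssr_id] = curve
        display = eval_curve(primary, red_truths, cfg.thresholds)
        write_curve_tsv(display, d / "curve.tsv")

    ref_id = _safe_name(cfg.reference_ssr)
    selection = None
    if ref_id in curves:
        selection = select_msrs(curves, curves[ref_id])
        selection.to_frame().to_csv(outdir / "selection.tsv", sep="\t", index=False)

    manifest = {
        "seqreduce_version": __version__,
        "config": asdict(cfg) | {"ssrs": list(cfg.ssrs), "thresholds": list(cfg.thresholds)},
        "n_reads": len(reads),
        "reductions_run": sorted(curves),
        "errors": errors,
        "selection_written": selection is not None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return curves
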