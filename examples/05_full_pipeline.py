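"""The full pipeline: reduce, map, translate, evaluate, select.

Runs raw, homopolymer compression, and the worked example reduction over
one simulated read set (synthetic mappings stand in for an external
mapper, so this runs with no binaries), then applies the three-list
selection procedure against the HPC mapq-60 reference point.
"""

import tempfile
from pathlib import Path

from seqreduce import (
    PipelineConfig,
    SimConfig,
    generate_genome,
    run_pipeline,
    simulate_reads,
)
from seqreduce.evaluation import write_truth_tsv
from seqreduce.io import write_fasta, write_fastq

workdir = Path(tempfile.mkdtemp(prefix="seqreduce_demo_"))
cfg = SimConfig(n_reads=2_000, seed=7)
genome, _repeats = generate_genome(cfg)
reads, truths = simulate_reads(genome, cfg)
write_fasta(genome, workdir / "genome.fa")
write_fastq(reads, workdir / "reads.fq")
write_truth_tsv(truths, workdir / "truth.tsv")

curves = run_pipeline(PipelineConfig(
    reference=str(workdir / "genome.fa"),
    reads=str(workdir / "reads.fq"),
    truth=str(workdir / "truth.tsv"),
    outdir=str(workdir / "run"),
    ssrs=("raw", "hpc", "worked_example"),
    wrong_rate=0.05,
    seed=8,
))

print(f"outputs under {workdir / 'run'}\n")
print("reduction        fraction@60   error@0")
for ssr_id, curve in curves.items():
    print(f"{ssr_id:15}  {curve.fraction_at(60):11.4f}   {curve.error_at(0):.4f}")
print("\nPer-reduction curve TSVs, reduced FASTA/FASTQ, position maps, PAF and")
print("the selection report (selection.tsv) were written to the run directory.")
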