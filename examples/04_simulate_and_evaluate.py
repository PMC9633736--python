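"""Simulate reads with known origins and score synthetic mappings.

The generator plants a 10% wrong-placement rate; the evaluation recovers
it as the mapping error rate at threshold 0, and with an informative
mapq model the error concentrates at low mapq, so the curve improves as
the threshold rises.
"""

from seqreduce import (
    SimConfig,
    eval_curve,
    generate_genome,
    simulate_reads,
    synth_mappings,
)

cfg = SimConfig(n_reads=5_000, seed=42)
genome, repeats = generate_genome(cfg)
reads, truths = simulate_reads(genome, cfg)
print(f"genome: {', '.join(f'{n} ({len(s)} bp)' for n, s in genome.items())}; "
      f"{len(repeats)} repeat copies; {len(reads)} reads")

lengths = {n: len(s) for n, s in genome.items()}
mappings = synth_mappings(truths, lengths, wrong_rate=0.10,
                          mapq_model="informative", seed=43)
curve = eval_curve(mappings, truths)

print("\nmapq threshold   fraction mapped   error rate")
for p in curve.points:
    print(f"{p.threshold:14d}   {p.fraction_mapped:15.4f}   {p.error_rate:10.4f}")
print("\nAt t=0 every read counts and the error rate estimates the planted 10%;"
      "\nraising the threshold trades mapped fraction for fewer wrong placements.")
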