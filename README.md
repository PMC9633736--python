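# seqreduce

Streaming sequence reductions for long-read mapping: a generalization of
homopolymer compression, with the machinery to construct, count, and
enumerate the reverse-complement-compatible family, translate
coordinates between original and reduced references, and evaluate and
select reductions by their effect on mapping accuracy.

## The idea

Long reads (Oxford Nanopore in particular) are dominated by homopolymer
expansion/contraction errors. The classic remedy is **homopolymer
compression (HPC)**: collapse every run of a repeated nucleotide to a
single occurrence before mapping, then lift the alignment coordinates
back. HPC is one member of a much larger family. An **order-ℓ streaming
sequence reduction (SSR)** is defined by a window function
g : Σ^ℓ → Σ ∪ {ε} over the DNA alphabet Σ, applied as

    f(x) = x[1..ℓ−1] · g(x[1..ℓ]) · g(x[2..ℓ+1]) ⋯ g(x[|x|−ℓ+1..|x|]),

i.e. copy the first ℓ−1 characters, slide a length-ℓ window, concatenate
the outputs, drop the ε's. HPC is the order-2 case with
g(x₁x₂) = x₂ if x₁ ≠ x₂ and ε otherwise. Some SSRs other than HPC turn
out to be better pre-processing transformations for mapping — these are
**mapping-friendly sequence reductions (MSRs)**.

The order-2 space holds 5¹⁶ ≈ 1.5·10¹¹ window functions — too many to
test. Two restrictions make it searchable:

1. **RC-core-insensitivity.** For mapping, a reduction must commute with
   reverse complement (RC). Requiring g to send every RC pair of ℓ-mers
   to complementary outputs (and self-RC ℓ-mers to ε) guarantees a
   near-commutation property — f(RC(r)) and RC(f(r)) agree once an ℓ−1
   prefix/suffix is trimmed — which suffices for long reads. At ℓ = 2 the
   four self-RC dinucleotides (AT, TA, GC, CG) are forced to ε and only
   i(2) = 6 free RC pairs remain.
2. **Output-relabeling equivalence.** Relabeling the output letters in a
   way that preserves Watson-Crick complementarity (A↔T, C↔G, or swapping
   the pairs) leaves mapping behavior essentially unchanged. Viewing g as
   a partition S₀…S_k of the free canonical ℓ-mers plus an injection
   t : {1..k} → Σ, the number of representatives is

       N(ℓ) = Σ_{k=1..4} C(ℓ,k) · o(k),

   where C(ℓ,k) is a Stirling-number sum counting the partitions and
   o(k) ∈ {1, 2, 3, 3} counts injection classes. N(2) = **2135**, small
   enough to enumerate and test exhaustively; N(3) ≈ 2.9·10²¹ is not.

The package implements the transformation engine with exact coordinate
lift-over, the census and enumerator above, the mapeval-style evaluation
(a placement is correct when intersection ≥ 10% of the union of the
mapped and true intervals; curves of fraction-mapped vs error-rate per
cumulative mapq threshold), the three-list selection procedure against
the HPC mapq-60 reference point, and a seeded synthetic-data generator
so the whole pipeline runs without downloads or external binaries.

## A worked example

```python
from seqreduce import get_worked_example, reduce_sequence, revcomp

f = get_worked_example()   # g(AA)=C, g(AC)=C, g(AG)=A, g(CA)=A, g(CC)=T, g(GA)=G
r = "TAAGTTGA"
print(reduce_sequence(f, r))             # TCAGGTG
print(revcomp(r))                        # TCAACTTA
print(reduce_sequence(f, revcomp(r)))    # TCACCTG
print(revcomp(reduce_sequence(f, r)))    # CACCTGA
```

f(RC(r)) ≠ RC(f(r)), but dropping the one-character prefix of the former
and suffix of the latter leaves `CACCTG` on both sides — the
near-commutation property that makes these reductions usable for
mapping. See `examples/` for narrative scripts covering reduction,
counting/enumeration, lift-over, evaluation, and the full pipeline
(`python examples/01_reduce_sequences.py`, …). The same functionality is
exposed as a CLI:

```sh
seqreduce count --order 2          # i(2)=6, C(2,k), o(k), N(2)=2135
seqreduce simulate --outdir sim --seed 1
seqreduce reduce --ssr hpc --in sim/reads.fq --out reads.hpc.fq
seqreduce pipeline --config run.json
```

## Layout

- `src/seqreduce/core.py` — reduction engine, RC predicates, position maps
- `src/seqreduce/enumeration.py` — partitions, injections, census, enumerator
- `src/seqreduce/named.py` — HPC / raw / worked-example tables, loader, MSR vetting
- `src/seqreduce/coordinates.py`, `paf.py` — lift-over, PAF/BED/posmap I/O
- `src/seqreduce/evaluation.py` — correctness, threshold curves, selection
- `src/seqreduce/simdata.py` — seeded synthetic genomes/reads/mappings
- `src/seqreduce/pipeline.py`, `cli.py` — the end-to-end run and its CLI
- `docs/methods.md` — models, conventions, parameter choices, limitations
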