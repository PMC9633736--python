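# Methods

## The reduction model

An order-ℓ streaming sequence reduction (SSR) is the sliding-window
transformation f built from a total window function
g : Σ^ℓ → Σ ∪ {ε}, Σ = {A, C, G, T}: the first ℓ−1 characters are copied
verbatim, then g is applied to every length-ℓ window left to right and
its outputs concatenated, ε outputs dropped. The package represents g as
an explicit table over all 4^ℓ ℓ-mers (`ReductionFunction`); totality
and the output alphabet are validated at construction. Strings shorter
than ℓ are returned unchanged (the formula degenerates to the copied
prefix).

**Coordinates.** Everything is 0-based, half-open, internally and in
PAF/BED I/O. Each emitted character records an *anchor*: the original
index of the character that produced it — prefix characters anchor to
themselves, a window's output anchors to the window's *last* character
(chosen to match homopolymer compression, whose output is the second
character of each dinucleotide window). Anchors are strictly increasing,
so a `PositionMap` supports binary-search lift-over in both directions.

**Out-of-alphabet policy.** The model assumes Σ = {A, C, G, T};
lowercase is uppercased. Any window containing another character (N,
IUPAC codes) emits nothing, and the offending character itself is
emitted verbatim exactly once — when it is the last character of its
window — acting as a deterministic context break that preserves sequence
landmarks. Real telomere-to-telomere references are essentially N-free,
so this policy matters only at the margins; it is documented rather than
configurable.

## Reverse-complement compatibility

A reduction is *RC-insensitive* when f(RC(x)) = RC(f(x)) for all x. That
quantification is over an infinite set, so `is_rc_insensitive` is a
bounded exhaustive verifier: it checks every DNA string up to a length
bound (default 8, i.e. 87 380 strings for order 2). A `False` is
definitive, a `True` is a bounded guarantee. HPC passes; the window-level
construction below generally does not.

A reduction is *RC-core-insensitive* when g itself sends every RC pair
of ℓ-mers to complementary outputs or both to ε, and every self-RC ℓ-mer
to ε (a single nucleotide cannot be its own reverse complement). This is
weaker than RC-insensitivity — the copied prefix breaks exact
commutation — but implies the near-commutation identity: trimming the
length-(ℓ−1) prefix of f(RC(r)) and suffix of RC(f(r)) yields equal
strings. The test suite verifies this identity exhaustively over all
strings of length ≤ 8 for 50 sampled restricted reductions. Note the
families are incomparable: HPC is RC-insensitive but not
RC-core-insensitive (it maps AT, TA, GC, CG to their second letters, not
to ε).

## The restricted census

An RC-core-insensitive order-ℓ function is determined by its outputs on
the *free canonical* ℓ-mers (the lexicographically smaller member of
each non-self-RC pair); there are i(ℓ) = 4^ℓ/2 of them for odd ℓ and
(4^ℓ − 4^{ℓ/2})/2 for even ℓ, so i(2) = 6. Such a function is a
partition of the free canonical ℓ-mers into S₀…S_k (S₀, possibly empty,
holds the ε inputs; S₁…S_k non-empty) plus an injection t of {1..k} into
the four nucleotides; k ≤ 4 is the *dimension*.

Two specifications are equivalent when S₀ agrees, the non-ε parts
coincide under a permutation π, and π preserves the pattern of
complementary output pairs. Because parts are disjoint (hence pairwise
distinct), π is unique when it exists, which `are_equivalent` exploits.
Counting:

- o(k), the injection classes per partition, is computed by enumerating
  all injections and grouping by complement pattern — never hard-coded,
  so the known values (1, 2, 3, 3) are a test, not an input.
- C(ℓ,k), the partitions, is a Stirling-number sum split on j = |S₀|:
  the j = 0 term is {i(ℓ) over k}, the middle terms are
  C(i(ℓ), j)·{i(ℓ)−j over k}, and j > i(ℓ)−k contributes nothing.
  Stirling numbers use the inclusion–exclusion closed form in exact
  integer arithmetic.
- N(ℓ) = Σ_k C(ℓ,k)·o(k). N(2) = 2135; N(3) ≈ 2.9·10²¹. N(4) is
  reported as the exact integer (≈ 9.4·10⁸²). Dimension k > 4 is
  impossible (only four output letters), so C(ℓ, k > 4) = 0.

The explicit enumerator (order 2 only; higher orders are refused with
the counts in the error message) walks dimensions ascending, then
partitions in a canonical recursive order, then injection classes by
sorted complement pattern. Within an equivalence class the
representative is the member whose serialized table (outputs in
lexicographic ℓ-mer order, ε as `-`) is lexicographically smallest — a
deterministic rule; any fixed rule would do. Formula and enumeration are
cross-checked in the tests and in `scripts/acceptance.py`.

## Lift-over

Interval translation onto the reduced sequence rounds inward: the image
of [a, b) is the reduced positions whose anchors lie in [a, b), possibly
empty when the interval covers only deleted characters. This makes the
translated truth interval a subset of the image of the true interval —
conservative for the overlap-based correctness test. The reverse
direction maps a reduced interval to [anchor(start), anchor(end−1)+1),
so reduced → original → reduced is exactly the identity. Reductions are
applied to the forward strand only (reverse-strand reads are the
mapper's business), so lift-over never reverse-complements coordinates.
Per-target maps are serialized as a run-length-encoded sidecar TSV.
CIGAR/cs-tag rewriting between coordinate spaces is out of scope; only
placements are evaluated.

## Evaluation and selection

A primary alignment is *correct* when the intersection of its mapped
interval and the read's true origin interval is at least 10% of their
union (different target name ⇒ incorrect; two empty intervals ⇒
incorrect). For a mapq threshold t, the curve point aggregates primary
alignments with mapq ≥ t: fraction mapped is relative to *all* simulated
reads — reads whose reduced form is empty can never map but stay in the
denominator — and the error rate is the incorrect fraction of those
alignments, defined as 0 when nothing is mapped (the convention keeps
sparse curves total). Records lacking a `tp:A:` tag count as primary.
Truth comparison is performed in reduced coordinate space (truth
intervals translated onto the reduced reference), matching the direction
in which the mapping was produced.

Selection against a reference point (HPC at mapq 60): a reduction's
*respective threshold* is the highest t at which it has strictly higher
fraction mapped and strictly lower error rate than the reference — ties
lose, and a reduction with no such t is discarded. *Percent better*
counts the thresholds 1..60 (denominator 60; threshold 0 excluded to
make the count exact) at which both strict inequalities hold. Three
top-20 lists are formed — highest fraction at the respective threshold,
lowest error at the respective threshold, highest percent-better — and
their union reported, with ties broken by (metric, then id). Three
best-in-category flags mirror the published MSR_F/E/P roles: highest
fraction at threshold 0, lowest error at the respective threshold, and
highest percent-better, each within the union. The repeat-region filter
keeps reads whose origin overlaps the merged repeat intervals by more
than 50% of the read length.

The published MSR_E/F/P dinucleotide tables are available only as
figures in their source, so they are not shipped; instead
`check_msr_constraints` vets a user-supplied candidate against the
textual facts (MSR_E maps AA→T hence TT→A; MSR_E and MSR_P map {CC,GG}
to ε; MSR_P assigns two free pairs, MSR_E and MSR_F one, to a G/C
output; all three are restricted SSRs).

## Synthetic data

The generator exists so every contract above is exercisable offline; it
is not a trained sequencing-error model. `SimConfig` defaults define the
fixture conditions: two 50 kb chromosomes with homopolymer enrichment
0.3 (each base repeats its predecessor with that probability, giving
geometric run lengths), four copies of a 2 kb repeat unit at 2%
divergence written over free gaps (coordinates emitted as BED), 2000
reads of mean length 1 kb (sd 300, minimum 200), 2% substitutions,
homopolymer length jitter (±1 per run with probability 0.1, never below
one base — invisible after HPC by construction), and equal strand
probabilities. Read names encode the truth as
`{id}!{target}!{start}!{end}!{strand}`, so no external truth format is
needed. Synthetic mappings place each read exactly on its truth interval
except for a controlled wrong-placement probability (displaced to a
non-overlapping locus); mapq comes from either a `uniform` model
(independent of correctness — the threshold-0 error rate estimates the
planted rate) or an `informative` model (correct ≈ N(55, 6), wrong ≈
N(8, 6), clipped to 0..60 — error concentrates at low mapq as with a
real mapper, making curves monotone in practice). Every generator is
deterministic under its seed.

What passing these fixtures does *not* show: realism of the error
process (no trained basecaller profile, no chimeras, no quality-score
structure), mapper behavior (synthetic mappings bypass alignment
entirely unless an external mapper template is configured), or that any
particular reduction helps on real genomes — the package evaluates
reductions; it does not certify them.

## Pipeline and problem sizes

`run_pipeline` chains reduce → map → translate → evaluate → select per
reduction under one run directory with a JSON manifest (version, config,
per-reduction errors). An external mapper is a command template
(`{ref}`, `{reads}`, `{paf}` placeholders) run as a subprocess — the
recorded default is minimap2's map-ont preset with `-c` — and a mapper
failure is logged per reduction without aborting the run; absent a
template, synthetic mappings are used with one shared seed so runs are
reproducible byte-for-byte. Selection curves are computed at all 61
integer thresholds; curve TSVs are written at the seven display
thresholds 60, 50, …, 0 by default.

Tests and examples run the pipeline at 300–2000 reads over 16–100 kb
genomes; the exhaustive string checks go to length 8 (length 10 for HPC
idempotence). These sizes were chosen so the full suite completes in
well under a minute per heavy test while still checking each property
exhaustively over its stated domain.

## Known limitations

- Enumeration is order-2 only; higher orders are counted, not searched.
- The bounded RC-insensitivity verifier cannot certify the property in
  general, only refute it.
- No quality recalibration through reduction (qualities are subset to
  the emitted positions) and no alphabet beyond DNA.
- The RC-insensitive family outside the core-insensitive construction
  (HPC among it) is recognized but not enumerated.
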