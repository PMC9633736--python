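"""Apply streaming sequence reductions to DNA strings.

Homopolymer compression collapses runs of a repeated base; the worked
RC-core-insensitive example reduction rewrites the sequence through its
dinucleotide table instead.  Both copy the first window-minus-one
characters and then stream the window function over the rest.
"""

from seqreduce import (
    apply_reduction,
    get_hpc,
    get_worked_example,
    reduce_sequence,
    revcomp,
)

hpc = get_hpc()
example = get_worked_example()

s = "AAAGGTTA"
reduced, posmap = apply_reduction(hpc, s)
print(f"HPC({s}) = {reduced}")
print(f"  anchors (original position of each reduced character): {posmap.anchors.tolist()}")

r = "TAAGTTGA"
print(f"f({r}) = {reduce_sequence(example, r)}")
print(f"RC({r}) = {revcomp(r)}")
print(f"f(RC(r)) = {reduce_sequence(example, revcomp(r))}")
print(f"RC(f(r)) = {revcomp(reduce_sequence(example, r))}")
print(
    "near-commutation (drop prefix of f(RC(r)), drop suffix of RC(f(r))): "
    f"{reduce_sequence(example, revcomp(r))[1:]} == "
    f"{revcomp(reduce_sequence(example, r))[:-1]}"
)
# The two trimmed strings agree even though f(RC(r)) != RC(f(r)): the
# copied prefix is the only obstruction, which is immaterial for long reads.
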