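"""Translate intervals between original and reduced coordinates.

A reduction deletes characters, so mapping results on a reduced
reference must be lifted back through the position map of deletions
before they mean anything on the original reference.
"""

from seqreduce import (
    GenomicInterval,
    apply_reduction,
    get_hpc,
    original_to_reduced,
    reduced_to_original,
)

s = "AAAGGTTA"
reduced, pm = apply_reduction(get_hpc(), s)
print(f"HPC({s}) = {reduced}; anchors = {pm.anchors.tolist()}")

iv = GenomicInterval("chr", 2, 8)
down = original_to_reduced(pm, iv)
print(f"original [{iv.start}, {iv.end}) -> reduced [{down.start}, {down.end})")

back = reduced_to_original(pm, down)
print(f"reduced [{down.start}, {down.end}) -> original [{back.start}, {back.end})")

deleted = original_to_reduced(pm, GenomicInterval("chr", 1, 2))
print(f"original [1, 2) covers only deleted positions -> empty "
      f"[{deleted.start}, {deleted.end})")
# Round trips from the reduced side are exact; original-side intervals can
# shrink because deleted positions have no reduced image.
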