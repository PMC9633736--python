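"""Count and enumerate the restricted order-2 reductions.

The restricted space — RC-core-insensitive window functions, one
representative per output-relabeling equivalence class — collapses the
5^16 possible order-2 window functions to 2135, small enough to test
every one of them against a mapper.
"""

from itertools import islice

from seqreduce import (
    build_count_table,
    count_restricted,
    enumerate_restricted,
    unrestricted_count,
)

ct = build_count_table(2)
print(f"free input pairs i(2) = {ct.free_inputs}")
for k in sorted(ct.partition_counts):
    print(f"  dimension {k}: C(2,{k}) = {ct.partition_counts[k]:4d} partitions x "
          f"o({k}) = {ct.injection_classes[k]} injection classes")
print(f"restricted census N(2) = {ct.total}")
print(f"unrestricted order-2 space 5^16 = {unrestricted_count(2):.1e}")
print(f"restricted N(3) = {count_restricted(3):.1e} (counting only; not enumerable)")

print("\nfirst three representatives (dimension 1, serialized tables):")
for spec, func in islice(enumerate_restricted(2), 3):
    print(f"  S0 = {sorted(spec.s0)!s:30} letters = {spec.letters} -> {func.serialized()}")
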