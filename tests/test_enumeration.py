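"""Counting and enumerating restricted SSRs.

Brute-force oracles (partition enumeration by exhaustive assignment,
interval arithmetic by explicit sets) are defined locally and kept
independent of the library code they check.
"""

import random
from itertools import product

import pytest

from seqreduce import (
    SSRSpec,
    are_equivalent,
    build_count_table,
    canonical_lmers,
    count_partitions,
    count_restricted,
    dimension,
    enumerate_restricted,
    free_input_count,
    injection_class_count,
    is_rc_core_insensitive,
    stirling2,
    unrestricted_count,
)


# ---------------------------------------------------------------------------
# Independent oracles

def brute_force_stirling2(n: int, k: int) -> int:
    """Count partitions of n labeled items into k non-empty unlabeled blocks
    by enumerating all label assignments and deduplicating block-set
    signatures."""
    seen = set()
    for assignment in product(range(k), repeat=n):
        if len(set(assignment)) != k:
            continue
        blocks = frozenset(
            frozenset(i for i in range(n) if assignment[i] == b) for b in range(k)
        )
        seen.add(blocks)
    return len(seen)


def brute_force_count_partitions(n_items: int, k: int) -> int:
    """Partitions into S0 (may be empty) plus k unordered non-empty blocks,
    by exhaustive assignment of items to labels {0..k}."""
    seen = set()
    for assignment in product(range(k + 1), repeat=n_items):
        if set(assignment) - {0} != set(range(1, k + 1)):
            continue
        s0 = frozenset(i for i in range(n_items) if assignment[i] == 0)
        blocks = frozenset(
            frozenset(i for i in range(n_items) if assignment[i] == b)
            for b in range(1, k + 1)
        )
        seen.add((s0, blocks))
    return len(seen)


# ---------------------------------------------------------------------------
# Canonical l-mers and degrees of freedom

def test_canonical_dinucleotides():
    self_rc, free_pairs = canonical_lmers(2)
    assert self_rc == ["AT", "CG", "GC", "TA"]
    assert free_pairs == [
        ("AA", "TT"), ("AC", "GT"), ("AG", "CT"),
        ("CA", "TG"), ("CC", "GG"), ("GA", "TC"),
    ]


def test_canonical_single_bases_and_trinucleotides():
    self_rc, free_pairs = canonical_lmers(1)
    assert self_rc == []
    assert free_pairs == [("A", "T"), ("C", "G")]
    self_rc3, free_pairs3 = canonical_lmers(3)
    assert len(self_rc3) == 0
    assert len(free_pairs3) == 32


@pytest.mark.parametrize("order,expected", [(2, 6), (3, 32), (4, 120)])
def test_free_input_count_parity_formula(order, expected):
    assert free_input_count(order) == expected
    assert free_input_count(order) == len(canonical_lmers(order)[1])


# ---------------------------------------------------------------------------
# Stirling numbers and partition counts

def test_stirling2_against_brute_force_and_edges():
    assert stirling2(6, 2) == brute_force_stirling2(6, 2) == 31
    assert all(stirling2(n, 1) == 1 for n in range(1, 10))
    assert stirling2(4, 4) == 1
    assert stirling2(0, 0) == 1
    assert stirling2(5, 7) == 0


def test_stirling2_recurrence():
    for n in range(1, 13):
        for k in range(1, n + 1):
            assert stirling2(n, k) == k * stirling2(n - 1, k) + stirling2(n - 1, k - 1)


def test_stirling2_large_arguments_are_exact():
    # closed form must stay exact far beyond machine precision
    assert stirling2(200, 2) == 2**199 - 1


@pytest.mark.parametrize("k", [1, 2, 3, 4])
def test_count_partitions_matches_brute_force(k):
    assert count_partitions(2, k) == brute_force_count_partitions(6, k)


def test_count_partitions_edge_cases():
    assert count_partitions(2, 5) == 0  # dimension is capped at 4
    with pytest.raises(ValueError):
        count_partitions(2, 0)


# ---------------------------------------------------------------------------
# Injection classes and the total count

def test_injection_class_counts():
    assert [injection_class_count(k) for k in (1, 2, 3, 4)] == [1, 2, 3, 3]
    assert sum(injection_class_count(k) for k in (1, 2, 3, 4)) == 9


def test_count_restricted_order_2():
    assert count_restricted(2) == 2135


def test_count_restricted_higher_orders_round_as_published():
    assert f"{count_restricted(3):.1e}" == "2.9e+21"
    assert f"{unrestricted_count(2):.1e}" == "1.5e+11"
    assert f"{unrestricted_count(3):.1e}" == "5.4e+44"


def test_count_table_is_internally_consistent():
    ct = build_count_table(2)
    assert ct.free_inputs == 6
    assert sum(ct.partition_counts[k] * ct.injection_classes[k] for k in range(1, 5)) == ct.total == 2135


# ---------------------------------------------------------------------------
# Explicit enumeration

def test_enumeration_yields_2135_valid_representatives(representatives):
    assert len(representatives) == 2135
    serials = {func.serialized() for _spec, func in representatives}
    assert len(serials) == 2135
    for _spec, func in representatives:
        assert is_rc_core_insensitive(func)
        for m in ("AT", "TA", "GC", "CG"):
            assert func.table[m] == ""


def test_enumeration_per_dimension_matches_formula(representatives):
    by_k = {}
    for spec, _func in representatives:
        by_k[spec.k] = by_k.get(spec.k, 0) + 1
    assert by_k == {k: count_partitions(2, k) * injection_class_count(k) for k in (1, 2, 3, 4)}


def test_enumeration_is_deterministic():
    first = next(iter(enumerate_restricted(2)))
    again = next(iter(enumerate_restricted(2)))
    assert first[0] == again[0]
    assert first[1].serialized() == again[1].serialized()


def test_enumeration_refuses_higher_orders():
    with pytest.raises(ValueError, match="too large"):
        list(enumerate_restricted(3))


def test_random_representative_pairs_are_non_equivalent(representatives):
    rng = random.Random(5)
    specs = [spec for spec, _ in representatives]
    for _ in range(1000):
        a, b = rng.sample(specs, 2)
        assert not are_equivalent(a, b)


# ---------------------------------------------------------------------------
# The equivalence relation

def _shuffled_variant(spec, rng):
    """An equivalent spec: permute block order, carrying the letters along."""
    order = list(range(spec.k))
    rng.shuffle(order)
    return SSRSpec(
        spec.order,
        spec.s0,
        tuple(spec.blocks[i] for i in order),
        tuple(spec.letters[i] for i in order),
    )


def _complement_swapped_variant(spec):
    """An equivalent spec: swap A<->T and C<->G in the outputs (the
    relabeling preserves every complementarity relation)."""
    swap = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return SSRSpec(spec.order, spec.s0, spec.blocks, tuple(swap[c] for c in spec.letters))


def test_equivalence_is_an_equivalence_relation(representatives):
    rng = random.Random(17)
    for spec, _func in rng.sample(representatives, 100):
        b = _shuffled_variant(spec, rng)
        c = _complement_swapped_variant(b)
        assert are_equivalent(spec, spec)  # reflexive
        assert are_equivalent(spec, b) and are_equivalent(b, spec)  # symmetric
        assert are_equivalent(b, c)
        assert are_equivalent(spec, c)  # transitive through b


def test_swapping_complementary_letters_preserves_equivalence():
    free = ["AA", "AC", "AG", "CA", "CC", "GA"]
    blocks = (frozenset(free[:3]), frozenset(free[3:]))
    a = SSRSpec(2, frozenset(), blocks, ("A", "T"))
    b = SSRSpec(2, frozenset(), blocks, ("T", "A"))
    assert are_equivalent(a, b)


def test_moving_an_lmer_into_s0_breaks_equivalence():
    free = ["AA", "AC", "AG", "CA", "CC", "GA"]
    a = SSRSpec(2, frozenset(), (frozenset(free),), ("A",))
    b = SSRSpec(2, frozenset({"AA"}), (frozenset(free[1:]),), ("A",))
    assert not are_equivalent(a, b)


def test_dimension_of_the_worked_example_partition():
    spec = SSRSpec(
        2,
        frozenset(),
        (
            frozenset({"AG", "CA"}),
            frozenset({"CC"}),
            frozenset({"AA", "AC"}),
            frozenset({"GA"}),
        ),
        ("A", "T", "C", "G"),
    )
    assert dimension(spec) == 4
    # expanding the spec reproduces the worked example's window function
    from seqreduce import get_worked_example

    assert spec.to_function().table == get_worked_example().table


def test_spec_validation_rejects_bad_partitions():
    free = ["AA", "AC", "AG", "CA", "CC", "GA"]
    with pytest.raises(ValueError, match="injection"):
        SSRSpec(2, frozenset(), (frozenset(free[:3]), frozenset(free[3:])), ("A", "A"))
    with pytest.raises(ValueError, match="cover"):
        SSRSpec(2, frozenset(), (frozenset(free[:3]),), ("A",))
    with pytest.raises(ValueError, match="non-empty"):
        SSRSpec(2, frozenset(free), (frozenset(),), ("A",))
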