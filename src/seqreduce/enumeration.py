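"""Construction, counting, and enumeration of restricted SSRs.

A *restricted* SSR is an RC-core-insensitive reduction taken up to output
relabelings that preserve Watson-Crick complementarity.  Because the
window function's value on an ``l``-mer determines its value on the
reverse complement, an RC-core-insensitive order-``l`` function is fully
specified by its outputs on the *free canonical* ``l``-mers: one member of
each reverse-complement pair, self-reverse-complementary ``l``-mers being
forced to epsilon.  Such a function can be viewed as

* a partition of the free canonical ``l``-mers into sets ``S0 .. Sk``
  (``S0``, possibly empty, collects the epsilon inputs; ``S1 .. Sk`` are
  non-empty), together with
* an injection ``t`` from ``{1..k}`` into ``{A, C, G, T}`` assigning an
  output letter to each non-epsilon part.  ``k`` is the *dimension*.

Two such specifications are equivalent when their ``S0`` agree, their
non-epsilon parts coincide up to a permutation, and the pattern of
complementary output pairs is preserved by that permutation.  The number
of injection classes per partition, ``o(k)``, and the number of
partitions, ``C(l, k)`` (a Stirling-number sum), give the total count of
representatives ``N(l) = sum_k C(l, k) * o(k)``.  For order 2 this count
is small enough (2135) to enumerate explicitly; for order >= 3 only the
count is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations, product
from math import comb, factorial
from typing import Iterator, Sequence

from .core import (
    DNA,
    EPSILON,
    ReductionFunction,
    all_lmers,
    complement,
    iscomp,
    revcomp,
)

__all__ = [
    "SSRSpec",
    "CountTable",
    "canonical_lmers",
    "free_canonical_lmers",
    "free_input_count",
    "stirling2",
    "count_partitions",
    "injection_class_count",
    "count_restricted",
    "unrestricted_count",
    "build_count_table",
    "enumerate_restricted",
    "are_equivalent",
    "dimension",
]

#: Highest possible dimension: the output alphabet has four nucleotides.
MAX_DIMENSION = 4


def canonical_lmers(order: int) -> tuple[list[str], list[tuple[str, str]]]:
    """Split the ``l``-mer space by its reverse-complement symmetry.

    Returns ``(self_rc, free_pairs)`` where ``self_rc`` lists the
    ``l``-mers equal to their own reverse complement (forced to epsilon in
    any RC-core-insensitive reduction) and ``free_pairs`` lists the
    remaining ``l``-mers grouped as ``(x, RC(x))`` with ``x``
    lexicographically smaller.  Both lists are sorted.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    self_rc: list[str] = []
    free_pairs: list[tuple[str, str]] = []
    for m in all_lmers(order) if order > 1 else list(DNA):
        r = revcomp(m)
        if m == r:
            self_rc.append(m)
        elif m < r:
            free_pairs.append((m, r))
    return self_rc, free_pairs


def free_canonical_lmers(order: int) -> list[str]:
    """The lexicographically smaller member of each free RC pair, sorted."""
    return [x for x, _ in canonical_lmers(order)[1]]


def free_input_count(order: int) -> int:
    """Degrees of freedom ``i(l)`` in choosing an RC-core-insensitive ``g``.

    ``i(l) = 4**l / 2`` for odd ``l`` (no self-reverse-complementary
    ``l``-mers) and ``(4**l - 4**(l/2)) / 2`` for even ``l``.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if order % 2:
        return 4**order // 2
    return (4**order - 4 ** (order // 2)) // 2


def stirling2(n: int, k: int) -> int:
    """Stirling number of the second kind, by inclusion-exclusion.

    Exact integer arithmetic: the number of ways to partition ``n``
    labeled elements into ``k`` non-empty unlabeled sets.
    """
    if n < 0 or k < 0:
        raise ValueError("n and k must be non-negative")
    if k > n:
        return 0
    if k == 0:
        return 1 if n == 0 else 0
    total = sum((-1) ** i * comb(k, i) * (k - i) ** n for i in range(k + 1))
    return total // factorial(k)


def count_partitions(order: int, k: int) -> int:
    """``C(l, k)``: partitions of the free canonical ``l``-mers into
    ``S0 .. Sk`` with ``S1 .. Sk`` non-empty (``S0`` may be empty).

    Splitting on ``j = |S0|``: the ``j = 0`` term is a bare Stirling
    number, ``1 <= j <= i(l) - k`` contributes a binomial times a Stirling
    number, and larger ``j`` contributes nothing (the remaining ``l``-mers
    cannot fill ``k`` non-empty sets).  ``k`` beyond the dimension cap of
    4, or beyond ``i(l)``, yields 0.
    """
    if k < 1:
        raise ValueError(f"dimension k must be >= 1, got {k}")
    if k > MAX_DIMENSION:
        return 0
    i = free_input_count(order)
    if k > i:
        return 0
    total = stirling2(i, k)
    for j in range(1, i - k + 1):
        total += comb(i, j) * stirling2(i - j, k)
    return total


def _injection_pattern(letters: Sequence[str]) -> frozenset[tuple[int, int]]:
    """Index pairs (i < j) whose output letters are Watson-Crick complements."""
    return frozenset(
        (i, j)
        for i, j in combinations(range(len(letters)), 2)
        if iscomp(letters[i], letters[j])
    )


def _injection_classes(k: int) -> dict[frozenset[tuple[int, int]], list[tuple[str, ...]]]:
    """Group all injections {1..k} -> {A,C,G,T} by their complement pattern."""
    groups: dict[frozenset[tuple[int, int]], list[tuple[str, ...]]] = {}
    for letters in permutations(DNA, k):
        groups.setdefault(_injection_pattern(letters), []).append(letters)
    return groups


def injection_class_count(k: int) -> int:
    """``o(k)``: equivalence classes of output injections at dimension ``k``.

    Computed by enumerating all injections from ``{1..k}`` into the four
    nucleotides and grouping them by which index pairs receive
    complementary letters.
    """
    if not 1 <= k <= MAX_DIMENSION:
        raise ValueError(f"dimension k must be in 1..{MAX_DIMENSION}, got {k}")
    return len(_injection_classes(k))


def count_restricted(order: int) -> int:
    """``N(l) = sum_{k=1..4} C(l, k) * o(k)``, as an exact integer."""
    if order < 2:
        raise ValueError("order must be >= 2")
    return sum(
        count_partitions(order, k) * injection_class_count(k)
        for k in range(1, MAX_DIMENSION + 1)
    )


def unrestricted_count(order: int) -> int:
    """Size of the unrestricted order-``l`` window-function space, ``5**(4**l)``."""
    return 5 ** (4**order)


@dataclass(frozen=True)
class CountTable:
    """All counting quantities for one order, exact integers throughout."""

    order: int
    free_inputs: int
    partition_counts: dict[int, int]
    injection_classes: dict[int, int]
    total: int

    def __post_init__(self) -> None:
        expected = sum(
            self.partition_counts[k] * self.injection_classes[k]
            for k in self.partition_counts
        )
        if expected != self.total:
            raise ValueError("total inconsistent with per-dimension counts")


def build_count_table(order: int) -> CountTable:
    ks = range(1, MAX_DIMENSION + 1)
    return CountTable(
        order=order,
        free_inputs=free_input_count(order),
        partition_counts={k: count_partitions(order, k) for k in ks},
        injection_classes={k: injection_class_count(k) for k in ks},
        total=count_restricted(order),
    )


@dataclass(frozen=True)
class SSRSpec:
    """A restricted SSR as (partition ``S0 .. Sk``, output injection ``t``).

    ``blocks`` holds ``S1 .. Sk`` (non-empty, disjoint); ``letters[i]`` is
    the output nucleotide of ``blocks[i]``.  ``s0`` collects the free
    canonical ``l``-mers mapped to epsilon; self-reverse-complementary
    ``l``-mers are implicit (always epsilon) and never listed.
    """

    order: int
    s0: frozenset[str]
    blocks: tuple[frozenset[str], ...]
    letters: tuple[str, ...]

    def __post_init__(self) -> None:
        k = len(self.blocks)
        if not 1 <= k <= MAX_DIMENSION:
            raise ValueError(f"dimension must be in 1..{MAX_DIMENSION}, got {k}")
        if len(self.letters) != k:
            raise ValueError("one output letter required per non-epsilon part")
        if len(set(self.letters)) != k or not set(self.letters) <= set(DNA):
            raise ValueError("output assignment must be an injection into {A,C,G,T}")
        if any(not b for b in self.blocks):
            raise ValueError("parts S1..Sk must be non-empty")
        parts = [self.s0, *self.blocks]
        union: set[str] = set()
        size = 0
        for p in parts:
            union |= p
            size += len(p)
        if size != len(union):
            raise ValueError("parts must be disjoint")
        if union != set(free_canonical_lmers(self.order)):
            raise ValueError("parts must cover exactly the free canonical l-mers")

    @property
    def k(self) -> int:
        return len(self.blocks)

    def to_function(self, name: str | None = None) -> ReductionFunction:
        """Expand the spec into a total window function.

        Free canonical ``l``-mers take their part's letter (epsilon for
        ``S0``); each reverse-complement partner takes the complementary
        letter; self-reverse-complementary ``l``-mers take epsilon.
        """
        table: dict[str, str] = {}
        for m in canonical_lmers(self.order)[0]:
            table[m] = EPSILON
        for m in self.s0:
            table[m] = EPSILON
            table[revcomp(m)] = EPSILON
        for block, letter in zip(self.blocks, self.letters):
            for m in block:
                table[m] = letter
                table[revcomp(m)] = complement(letter)
        return ReductionFunction(order=self.order, table=table, name=name)

    def comp_pattern(self) -> frozenset[tuple[int, int]]:
        """Index pairs of parts whose output letters are complementary."""
        return _injection_pattern(self.letters)


def dimension(spec: SSRSpec) -> int:
    """Number of distinct nucleotides the spec can output, ``k`` in 1..4."""
    return spec.k


def are_equivalent(a: SSRSpec, b: SSRSpec) -> bool:
    """Decide SSR equivalence.

    True iff the orders and dimensions agree, ``S0`` coincide, and some
    permutation ``pi`` of ``{1..k}`` aligns the non-epsilon parts while
    preserving the pattern of complementary output pairs:
    ``ISCOMP(t(i), t(j)) == ISCOMP(t'(pi(i)), t'(pi(j)))`` for all
    ``i < j``.
    """
    if a.order != b.order or a.k != b.k:
        return False
    if a.s0 != b.s0:
        return False
    k = a.k
    b_index = {block: i for i, block in enumerate(b.blocks)}
    if set(a.blocks) != set(b_index):
        return False
    # blocks are disjoint hence pairwise distinct: pi is unique
    pi = [b_index[block] for block in a.blocks]
    for i, j in combinations(range(k), 2):
        if iscomp(a.letters[i], a.letters[j]) != iscomp(
            b.letters[pi[i]], b.letters[pi[j]]
        ):
            return False
    return True


def _set_partitions(items: Sequence[str], k: int) -> Iterator[list[list[str]]]:
    """All partitions of ``items`` into exactly ``k`` non-empty blocks.

    Standard recursion mirroring S(n,k) = S(n-1,k-1) + k*S(n-1,k); each
    unordered partition is produced exactly once, deterministically.
    """
    n = len(items)
    if k == 0:
        if n == 0:
            yield []
        return
    if n < k:
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest, k - 1):
        yield [[first]] + part
    for part in _set_partitions(rest, k):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]


def enumerate_restricted(order: int = 2) -> Iterator[tuple[SSRSpec, ReductionFunction]]:
    """Yield one representative per equivalence class of restricted SSRs.

    Only order 2 is enumerable: the restricted spaces at order 3 and 4
    hold roughly ``N(3)`` and ``N(4)`` classes (10^21 and beyond), far too
    many to stream.  Enumeration order is deterministic: dimension ``k``
    ascending, then partition in the canonical generation order, then
    injection class by sorted complement pattern.  The representative of
    each class is the member whose serialized table is lexicographically
    smallest.
    """
    if order != 2:
        raise ValueError(
            "search space too large: enumeration is only supported for order 2 "
            f"(N(3) = {count_restricted(3):.1e}, N(4) = {count_restricted(4):.1e} "
            "equivalence classes)"
        )
    items = free_canonical_lmers(order)
    for k in range(1, MAX_DIMENSION + 1):
        classes = _injection_classes(k)
        patterns = sorted(classes, key=lambda p: sorted(p))
        for j in range(0, len(items) - k + 1):
            for s0 in combinations(items, j):
                remaining = [m for m in items if m not in s0]
                for blocks in _set_partitions(remaining, k):
                    block_sets = tuple(frozenset(b) for b in blocks)
                    s0_set = frozenset(s0)
                    for pattern in patterns:
                        best: tuple[str, SSRSpec, ReductionFunction] | None = None
                        for letters in classes[pattern]:
                            spec = SSRSpec(order, s0_set, block_sets, tuple(letters))
                            func = spec.to_function()
                            key = func.serialized()
                            if best is None or key < best[0]:
                                best = (key, spec, func)
                        assert best is not None
                        yield best[1], best[2]
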