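"""Ready-made reductions and the loader/registry for user-supplied tables.

Ships the three reductions used throughout the literature and this
package's own documentation:

* ``hpc`` — homopolymer compression (collapse runs of a repeated base);
* ``raw`` — the identity transformation, expressed as an order-2 SSR;
* ``worked_example`` — the worked RC-core-insensitive example reduction
  built from the canonical assignments g(AA)=C, g(AC)=C, g(AG)=A,
  g(CA)=A, g(CC)=T, g(GA)=G and their reverse-complement completion.

The published MSR_E / MSR_F / MSR_P dinucleotide tables are only
available graphically in their source, so they are not hard-coded here;
instead :func:`check_msr_constraints` verifies a user-supplied candidate
table against the textual facts known about each of them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Mapping

from .core import (
    DNA,
    EPSILON,
    ReductionFunction,
    all_lmers,
    complement,
    is_rc_core_insensitive,
    read_table,
    revcomp,
)
from .enumeration import canonical_lmers, free_canonical_lmers

__all__ = [
    "get_hpc",
    "get_identity",
    "get_worked_example",
    "from_canonical_assignments",
    "load_reduction",
    "resolve_reduction",
    "check_msr_constraints",
    "REGISTRY",
]


def get_hpc() -> ReductionFunction:
    """Homopolymer compression as an order-2 reduction.

    Equal-letter dinucleotides map to epsilon, all others to their second
    letter, so each run of a repeated nucleotide survives as a single
    occurrence.
    """
    table = {a + b: (EPSILON if a == b else b) for a in DNA for b in DNA}
    return ReductionFunction(order=2, table=table, name="hpc")


def get_identity() -> ReductionFunction:
    """The identity transformation ("raw"), expressed as an order-2 SSR.

    Every dinucleotide maps to its second letter: the copied first
    character plus the stream of second characters reproduces the input.
    """
    table = {a + b: b for a in DNA for b in DNA}
    return ReductionFunction(order=2, table=table, name="raw")


def from_canonical_assignments(
    assignments: Mapping[str, str], order: int = 2, name: str | None = None
) -> ReductionFunction:
    """Build an RC-core-insensitive reduction from its free choices.

    ``assignments`` gives the output (nucleotide or ``""`` for epsilon)
    for every free canonical ``l``-mer; reverse-complement partners
    receive the complementary output and self-reverse-complementary
    ``l``-mers are forced to epsilon.
    """
    free = free_canonical_lmers(order)
    extra = sorted(set(assignments) - set(free))
    if extra:
        raise ValueError(
            f"assignments must be on free canonical l-mers only; got {extra[0]!r}"
        )
    missing = sorted(set(free) - set(assignments))
    if missing:
        raise ValueError(f"missing assignment for free canonical l-mer {missing[0]!r}")
    table: dict[str, str] = {m: EPSILON for m in canonical_lmers(order)[0]}
    for m, out in assignments.items():
        table[m] = out
        table[revcomp(m)] = complement(out) if out else EPSILON
    return ReductionFunction(order=order, table=table, name=name)


def get_worked_example() -> ReductionFunction:
    """The worked example of the RC-core-insensitive construction.

    Canonical choices g(AA)=C, g(AC)=C, g(AG)=A, g(CA)=A, g(CC)=T,
    g(GA)=G, completed by complementarity (so g(TT)=G, g(GT)=G, g(CT)=T,
    ...) with AT, TA, GC, CG mapped to epsilon.
    """
    return from_canonical_assignments(
        {"AA": "C", "AC": "C", "AG": "A", "CA": "A", "CC": "T", "GA": "G"},
        name="worked_example",
    )


#: Built-in reductions addressable by name from the CLI and the pipeline.
REGISTRY: dict[str, Callable[[], ReductionFunction]] = {
    "hpc": get_hpc,
    "raw": get_identity,
    "identity": get_identity,
    "worked_example": get_worked_example,
}


def load_reduction(path: str | Path) -> ReductionFunction:
    """Load and validate a user-supplied reduction table (TSV or JSON).

    Totality and output-alphabet violations are reported with row-level
    messages by the underlying reader.  RC-core-insensitivity is checked
    and recorded in the returned function's name suffix, but is not
    required: non-core-insensitive tables (e.g. HPC itself) are legal.
    """
    f = read_table(path)
    if not is_rc_core_insensitive(f):
        f = ReductionFunction(order=f.order, table=f.table, name=f"{f.name} (not RC-core-insensitive)")
    return f


def resolve_reduction(name_or_path: str) -> ReductionFunction:
    """Resolve a registry name (``hpc``, ``raw``, ``worked_example``) or a path."""
    key = name_or_path.lower()
    if key in REGISTRY:
        return REGISTRY[key]()
    path = Path(name_or_path)
    if path.exists():
        return load_reduction(path)
    raise ValueError(
        f"unknown reduction {name_or_path!r}: not a registry name "
        f"({', '.join(sorted(set(REGISTRY)))}) and no such file"
    )


def _gc_pair_count(f: ReductionFunction) -> int:
    """Free RC pairs whose outputs are the G/C complement pair."""
    return sum(1 for m in free_canonical_lmers(f.order) if f.table[m] in ("G", "C"))


# Textual facts known about the three published MSRs, used to vet a
# candidate table claiming one of those names.
_MSR_RULES: dict[str, list[tuple[str, Callable[[ReductionFunction], bool]]]] = {
    "msr_e": [
        ("maps AA to T (hence TT to A)", lambda f: f.table["AA"] == "T" and f.table["TT"] == "A"),
        ("maps the {CC,GG} pair to epsilon", lambda f: f.table["CC"] == EPSILON == f.table["GG"]),
        ("assigns exactly 1 free pair to a G/C output", lambda f: _gc_pair_count(f) == 1),
    ],
    "msr_f": [
        ("assigns exactly 1 free pair to a G/C output", lambda f: _gc_pair_count(f) == 1),
    ],
    "msr_p": [
        ("maps the {CC,GG} pair to epsilon", lambda f: f.table["CC"] == EPSILON == f.table["GG"]),
        ("assigns exactly 2 free pairs to a G/C output", lambda f: _gc_pair_count(f) == 2),
    ],
}


def check_msr_constraints(f: ReductionFunction, which: str) -> list[str]:
    """Vet a candidate order-2 table against the known facts for an MSR name.

    ``which`` is one of ``msr_e``, ``msr_f``, ``msr_p``.  Returns the list
    of violated constraints (empty when the candidate is admissible).  All
    three MSRs are restricted SSRs, so RC-core-insensitivity is always
    required.
    """
    key = which.lower()
    if key not in _MSR_RULES:
        raise ValueError(f"unknown MSR name {which!r}; expected one of {sorted(_MSR_RULES)}")
    if f.order != 2:
        return [f"{which} is an order-2 reduction, got order {f.order}"]
    violations = []
    if not is_rc_core_insensitive(f):
        violations.append("is not RC-core-insensitive")
    for description, predicate in _MSR_RULES[key]:
        if not predicate(f):
            violations.append(description)
    return violations
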