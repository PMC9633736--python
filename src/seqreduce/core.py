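"""Streaming sequence reductions (SSRs).

An order-``l`` streaming sequence reduction slides a window of length
``l`` over a DNA string and, after copying the first ``l - 1`` characters
verbatim, concatenates the outputs of a window function
``g : Sigma^l -> Sigma + {epsilon}`` applied to every window, dropping the
empty outputs.  Homopolymer compression (HPC) is the best-known member of
this family: its window function emits the second character of a
dinucleotide window unless the two characters are equal, in which case it
emits nothing, so runs of a repeated nucleotide collapse to a single
occurrence (``AAAGGTTA`` becomes ``AGTA``).

This module provides the :class:`ReductionFunction` container for the
window function, :func:`apply_reduction` (the sliding-window wrapper,
which also records a :class:`PositionMap` from reduced to original
coordinates), reverse-complement utilities, and the two
reverse-complement-compatibility predicates used to restrict the search
space of reductions:

* *RC-insensitive*: ``f(RC(x)) == RC(f(x))`` for every string ``x``.
* *RC-core-insensitive*: the window function sends every
  reverse-complement pair of ``l``-mers to complementary outputs (or both
  to epsilon), and every self-reverse-complementary ``l``-mer to epsilon.

RC-core-insensitivity is weaker than RC-insensitivity (the copied prefix
breaks exact commutation with reverse complement), but it guarantees the
near-commutation identity: dropping the length ``l - 1`` prefix of
``f(RC(r))`` and the length ``l - 1`` suffix of ``RC(f(r))`` yields equal
strings, which is all a long-read mapper needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "DNA",
    "EPSILON",
    "ReductionFunction",
    "PositionMap",
    "revcomp",
    "complement",
    "iscomp",
    "all_lmers",
    "apply_reduction",
    "reduce_sequence",
    "is_rc_core_insensitive",
    "is_rc_insensitive",
    "read_table",
    "write_table",
]

#: The DNA alphabet, in the fixed order used for table serialization.
DNA = "ACGT"

#: Internal representation of the empty output character epsilon.
EPSILON = ""

#: Symbol used for epsilon in TSV/JSON serializations.
EPSILON_TEXT = "-"

_ACGT = frozenset(DNA)

# Watson-Crick complement, extended to the IUPAC ambiguity codes so that
# reverse-complementing a real reference never fails on an N.
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMP_TRANS = str.maketrans(_COMPLEMENT)


def complement(base: str) -> str:
    """Watson-Crick complement of a single nucleotide (IUPAC tolerated)."""
    b = base.upper()
    try:
        return _COMPLEMENT[b]
    except KeyError:
        raise ValueError(f"no defined complement for character {base!r}") from None


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string.

    The input is uppercased first.  Characters outside the IUPAC nucleotide
    alphabet are rejected with a message naming the offending character.
    """
    s = s.upper()
    bad = set(s) - _COMPLEMENT.keys()
    if bad:
        raise ValueError(
            f"no defined complement for character {min(bad)!r} in sequence"
        )
    return s.translate(_COMP_TRANS)[::-1]


def iscomp(x: str, y: str) -> bool:
    """True iff ``x`` and ``y`` are Watson-Crick complements.

    Both arguments are single output symbols from ``{A, C, G, T, epsilon}``;
    epsilon is not a nucleotide and complements nothing, including itself.
    """
    return {x, y} in ({"A", "T"}, {"C", "G"})


def all_lmers(order: int) -> list[str]:
    """All ``4**order`` DNA ``l``-mers in lexicographic order."""
    return ["".join(p) for p in product(DNA, repeat=order)]


@dataclass(frozen=True)
class ReductionFunction:
    """An order-``l`` window function ``g`` mapping every ``l``-mer to a
    single nucleotide or to epsilon (represented as the empty string).

    The table must be total: exactly one entry per ``l``-mer over
    ``{A, C, G, T}``.
    """

    order: int
    table: Mapping[str, str]
    name: str | None = None

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError(f"order must be >= 2, got {self.order}")
        expected = all_lmers(self.order)
        keys = set(self.table)
        if keys != set(expected):
            missing = sorted(set(expected) - keys)
            extra = sorted(keys - set(expected))
            parts = []
            if missing:
                parts.append(f"missing {len(missing)} l-mer(s), e.g. {missing[0]!r}")
            if extra:
                parts.append(f"unexpected key(s), e.g. {extra[0]!r}")
            raise ValueError("reduction table is not total: " + "; ".join(parts))
        bad = {k: v for k, v in self.table.items() if v not in ("A", "C", "G", "T", EPSILON)}
        if bad:
            k, v = next(iter(bad.items()))
            raise ValueError(f"invalid output {v!r} for l-mer {k!r}")
        object.__setattr__(self, "table", dict(self.table))

    def __call__(self, lmer: str) -> str:
        return self.table[lmer]

    def serialized(self) -> str:
        """Outputs concatenated in lexicographic l-mer order, epsilon as '-'.

        This string is a canonical fingerprint of the function, used for
        deterministic representative selection and ordering.
        """
        return "".join(self.table[m] or EPSILON_TEXT for m in all_lmers(self.order))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReductionFunction):
            return NotImplemented
        return self.order == other.order and self.table == other.table

    def __hash__(self) -> int:
        return hash((self.order, self.serialized()))


@dataclass(frozen=True)
class PositionMap:
    """Correspondence between reduced-sequence and original-sequence indices.

    ``anchors[i]`` is the 0-based index, on the original sequence, of the
    character that produced reduced position ``i``: prefix characters anchor
    to themselves and each window output anchors to the last character of
    its window.  Anchors are strictly increasing, so interval lift-over in
    either direction is a binary search.
    """

    anchors: np.ndarray
    original_length: int

    def __post_init__(self) -> None:
        a = np.asarray(self.anchors, dtype=np.int64)
        object.__setattr__(self, "anchors", a)
        if a.size:
            if np.any(np.diff(a) <= 0):
                raise ValueError("anchors must be strictly increasing")
            if a[0] < 0 or a[-1] >= self.original_length:
                raise ValueError("anchors out of [0, original_length)")

    @property
    def reduced_length(self) -> int:
        return int(self.anchors.size)

    def anchor(self, i: int) -> int:
        return int(self.anchors[i])


def reduce_sequence(f: ReductionFunction, s: str) -> str:
    """Apply the reduction and return only the reduced string.

    Faster than :func:`apply_reduction` when the position map is not
    needed (exhaustive property checks, enumeration screens).
    """
    s = s.upper()
    l = f.order
    if len(s) < l:
        return s
    table = f.table
    if _ACGT.issuperset(s):
        parts = [s[: l - 1]]
        parts.extend(table[s[p - l + 1 : p + 1]] for p in range(l - 1, len(s)))
        return "".join(parts)
    return apply_reduction(f, s)[0]


def apply_reduction(f: ReductionFunction, s: str) -> tuple[str, PositionMap]:
    """Transform ``s`` with the order-``l`` reduction ``f``.

    The output is the first ``l - 1`` characters of ``s`` followed by the
    window outputs, epsilon outputs dropped.  Strings shorter than ``l``
    are returned unchanged.  A window containing a non-ACGT character
    emits nothing, except that the offending character itself is emitted
    verbatim once (when it is the last character of its window), acting as
    a context break that preserves sequence landmarks.

    Returns the reduced string together with its :class:`PositionMap`.
    """
    s = s.upper()
    l = f.order
    n = len(s)
    if n < l:
        return s, PositionMap(np.arange(n, dtype=np.int64), n)

    out: list[str] = list(s[: l - 1])
    anchors: list[int] = list(range(l - 1))
    table = f.table

    if _ACGT.issuperset(s):
        for p in range(l - 1, n):
            o = table[s[p - l + 1 : p + 1]]
            if o:
                out.append(o)
                anchors.append(p)
    else:
        # count of non-ACGT characters in a prefix, to test windows in O(1)
        bad = np.frombuffer(s.encode("ascii", "replace"), dtype=np.uint8)
        isbad = ~np.isin(bad, np.frombuffer(b"ACGT", dtype=np.uint8))
        badcum = np.concatenate(([0], np.cumsum(isbad)))
        for p in range(l - 1, n):
            if badcum[p + 1] - badcum[p - l + 1] > 0:
                if isbad[p]:
                    out.append(s[p])
                    anchors.append(p)
            else:
                o = table[s[p - l + 1 : p + 1]]
                if o:
                    out.append(o)
                    anchors.append(p)

    return "".join(out), PositionMap(np.asarray(anchors, dtype=np.int64), n)


def is_rc_core_insensitive(f: ReductionFunction) -> bool:
    """Check the window-level reverse-complement condition on ``g``.

    For every ``l``-mer ``x`` with reverse complement ``y``, either
    ``g(x)`` and ``g(y)`` are complementary nucleotides or both are
    epsilon; self-reverse-complementary ``l``-mers must map to epsilon
    (a single nucleotide cannot be its own reverse complement).
    """
    table = f.table
    for x in all_lmers(f.order):
        y = revcomp(x)
        gx, gy = table[x], table[y]
        if x == y:
            if gx != EPSILON:
                return False
        elif not (gx == gy == EPSILON or iscomp(gx, gy)):
            return False
    return True


def is_rc_insensitive(f: ReductionFunction, max_len: int = 8) -> bool:
    """Bounded exhaustive verifier of ``f(RC(x)) == RC(f(x))``.

    True RC-insensitivity quantifies over all strings; this checks every
    DNA string of length 1..``max_len`` (the default covers all strings up
    to length 8 for order-2 reductions, 87380 strings).  A ``False`` is
    definitive; a ``True`` is a bounded guarantee.
    """
    if max_len < f.order:
        raise ValueError("max_len must be >= the reduction order")
    for length in range(1, max_len + 1):
        for tup in product(DNA, repeat=length):
            s = "".join(tup)
            if reduce_sequence(f, revcomp(s)) != revcomp(reduce_sequence(f, s)):
                return False
    return True


# ---------------------------------------------------------------------------
# Serialization: TSV (one row per l-mer) and JSON, epsilon written as '-'.

def write_table(f: ReductionFunction, path: str | Path) -> None:
    """Write a reduction table, format chosen by extension (.json else TSV).

    Rows are sorted lexicographically by ``l``-mer; epsilon is written
    as ``-``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "order": f.order,
            "name": f.name,
            "table": {m: (f.table[m] or EPSILON_TEXT) for m in all_lmers(f.order)},
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        lines = [f"{m}\t{f.table[m] or EPSILON_TEXT}" for m in all_lmers(f.order)]
        path.write_text("\n".join(lines) + "\n")


def _parse_output(sym: str, where: str) -> str:
    if sym == EPSILON_TEXT:
        return EPSILON
    if sym in ("A", "C", "G", "T"):
        return sym
    raise ValueError(f"{where}: invalid output symbol {sym!r} (expected A/C/G/T/-)")


def read_table(path: str | Path, name: str | None = None) -> ReductionFunction:
    """Load a reduction table from TSV or JSON.

    Validates totality (every ``l``-mer present exactly once) and the
    output alphabet, reporting errors with the offending row or ``l``-mer.
    """
    path = Path(path)
    raw: dict[str, str] = {}
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        items = payload["table"].items()
        name = name or payload.get("name")
        for lmer, sym in items:
            lmer = lmer.upper()
            if lmer in raw:
                raise ValueError(f"{path}: duplicate l-mer {lmer!r}")
            raw[lmer] = _parse_output(sym, f"{path} key {lmer!r}")
    else:
        for idx, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path} line {idx}: expected 2 columns, got {len(fields)}")
            lmer, sym = fields[0].upper(), fields[1]
            if lmer in raw:
                raise ValueError(f"{path} line {idx}: duplicate l-mer {lmer!r}")
            raw[lmer] = _parse_output(sym, f"{path} line {idx}")
    if not raw:
        raise ValueError(f"{path}: empty reduction table")
    order = len(next(iter(raw)))
    missing = sorted(set(all_lmers(order)) - raw.keys())
    if missing:
        raise ValueError(f"{path}: missing l-mer(s): {', '.join(missing[:8])}")
    return ReductionFunction(order=order, table=raw, name=name or path.stem)
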