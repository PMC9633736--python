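"""Synthetic genomes, reads, and mappings for exercising the pipeline.

The generator emulates the features of long-read data that matter to
sequence reductions: a reference with enriched homopolymer runs and a
diverged tandem-style repeat cassette, reads carrying their true origin
in their names, an error process of substitutions plus per-run
homopolymer expansions/contractions (the error mode homopolymer
compression exists to absorb), and synthetic PAF mappings with a
controlled wrong-placement rate and a parameterized mapq distribution.
It deliberately does not model a trained sequencing-error profile,
quality-score realism, or chimeric reads; it is a fixture generator whose
every output is deterministic under its seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .core import DNA, revcomp
from .coordinates import GenomicInterval
from .evaluation import ReadTruth
from .paf import MappingRecord

__all__ = ["SimConfig", "generate_genome", "simulate_reads", "synth_mappings"]

_RUN_RE = re.compile(r"(.)\1*")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic fixtures.

    Defaults describe a small two-chromosome 100 kb genome read at the
    scale of a desk experiment: 2000 reads of mean length 1 kb with a 2%
    substitution rate and homopolymer-length jitter on one run in ten,
    mimicking the dominant long-read error mode.
    """

    chrom_length: int = 50_000
    n_chroms: int = 2
    homopolymer_rate: float = 0.3  # P(repeat the previous base) per position
    repeat_unit_length: int = 2_000
    repeat_copies: int = 4
    repeat_divergence: float = 0.02
    n_reads: int = 2_000
    read_length_mean: float = 1_000.0
    read_length_sd: float = 300.0
    read_length_min: int = 200
    substitution_prob: float = 0.02
    homopolymer_indel_prob: float = 0.1  # per homopolymer run
    reverse_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "homopolymer_rate",
            "repeat_divergence",
            "substitution_prob",
            "homopolymer_indel_prob",
            "reverse_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("chrom_length", "n_chroms", "read_length_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _random_sequence(rng: np.random.Generator, length: int, hp_rate: float) -> str:
    """Uniform DNA with geometric homopolymer enrichment.

    At each position, with probability ``hp_rate`` the previous base is
    repeated; otherwise a base is drawn uniformly.  ``hp_rate = 0`` gives
    an i.i.d. uniform sequence.
    """
    bases = rng.integers(0, 4, size=length)
    if hp_rate > 0:
        repeat = rng.random(size=length) < hp_rate
        out = np.empty(length, dtype=np.int64)
        prev = bases[0]
        out[0] = prev
        for i in range(1, length):
            prev = prev if repeat[i] else bases[i]
            out[i] = prev
        bases = out
    return "".join(DNA[b] for b in bases)


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        arr[i] = DNA[(DNA.index(arr[i]) + rng.integers(1, 4)) % 4]
    return "".join(arr)


def generate_genome(cfg: SimConfig) -> tuple[dict[str, str], list[GenomicInterval]]:
    """Deterministic synthetic genome plus the BED of its repeat cassette.

    Each chromosome is a homopolymer-enriched random sequence; diverged
    copies of one repeat unit are written over non-overlapping slices and
    their coordinates returned as intervals (empty with zero copies).
    """
    rng = np.random.default_rng(cfg.seed)
    genome = {
        f"chr{i + 1}": _random_sequence(rng, cfg.chrom_length, cfg.homopolymer_rate)
        for i in range(cfg.n_chroms)
    }
    repeats: list[GenomicInterval] = []
    if cfg.repeat_copies > 0 and cfg.repeat_unit_length > 0:
        unit = _random_sequence(rng, cfg.repeat_unit_length, cfg.homopolymer_rate)
        occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in genome}
        names = sorted(genome)
        unit_len = cfg.repeat_unit_length
        for _ in range(cfg.repeat_copies):
            # sample a start uniformly over the free gaps of all chromosomes
            slots: list[tuple[str, int, int]] = []  # (chrom, lo, hi) of valid starts
            for name in names:
                gaps = []
                prev = 0
                for s, e in sorted(occupied[name]):
                    gaps.append((prev, s))
                    prev = e
                gaps.append((prev, len(genome[name])))
                for lo, hi in gaps:
                    if hi - lo >= unit_len:
                        slots.append((name, lo, hi - unit_len))
            if not slots:
                raise ValueError("genome too small for the requested repeat copies")
            weights = np.array([hi - lo + 1 for _n, lo, hi in slots], dtype=float)
            name, lo, hi = slots[rng.choice(len(slots), p=weights / weights.sum())]
            start = int(rng.integers(lo, hi + 1))
            end = start + unit_len
            occupied[name].append((start, end))
            copy = _diverge(rng, unit, cfg.repeat_divergence)
            genome[name] = genome[name][:start] + copy + genome[name][end:]
            repeats.append(GenomicInterval(name, start, end))
        repeats.sort(key=lambda iv: (iv.name, iv.start))
    return genome, repeats


def _apply_errors(rng: np.random.Generator, seq: str, cfg: SimConfig) -> str:
    """Per-run homopolymer length jitter, then substitutions."""
    if cfg.homopolymer_indel_prob > 0:
        parts = []
        for m in _RUN_RE.finditer(seq):
            run = m.group(0)
            if rng.random() < cfg.homopolymer_indel_prob:
                if len(run) == 1 or rng.random() < 0.5:
                    run = run + run[0]  # expansion
                else:
                    run = run[:-1]  # contraction (never below one base)
            parts.append(run)
        seq = "".join(parts)
    if cfg.substitution_prob > 0:
        seq = _diverge(rng, seq, cfg.substitution_prob)
    return seq


def simulate_reads(
    genome: Mapping[str, str], cfg: SimConfig
) -> tuple[list[tuple[str, str, str]], list[ReadTruth]]:
    """Error-bearing reads with their truth encoded in the read names.

    Read names follow ``{id}!{target}!{start}!{end}!{strand}``; the truth
    interval is the error-free origin on the forward reference.
    Reverse-strand reads are reverse-complemented before errors are
    applied, so errors live on the read as sequenced.  Qualities are a
    constant placeholder.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    names = sorted(genome)
    lengths = np.array([len(genome[n]) for n in names], dtype=float)
    if cfg.read_length_min > lengths.max():
        raise ValueError("read_length_min exceeds the longest chromosome")
    weights = lengths / lengths.sum()

    reads: list[tuple[str, str, str]] = []
    truths: list[ReadTruth] = []
    for i in range(cfg.n_reads):
        target = names[rng.choice(len(names), p=weights)]
        chrom_len = len(genome[target])
        length = int(rng.normal(cfg.read_length_mean, cfg.read_length_sd))
        length = max(cfg.read_length_min, min(length, chrom_len))
        start = int(rng.integers(0, chrom_len - length + 1))
        end = start + length
        strand = "-" if rng.random() < cfg.reverse_prob else "+"
        origin = genome[target][start:end]
        seq = revcomp(origin) if strand == "-" else origin
        seq = _apply_errors(rng, seq, cfg)
        name = f"r{i:06d}!{target}!{start}!{end}!{strand}"
        reads.append((name, seq, "I" * len(seq)))
        truths.append(ReadTruth(name, GenomicInterval(target, start, end, strand)))
    return reads, truths


def synth_mappings(
    truths: Sequence[ReadTruth],
    target_lengths: Mapping[str, int],
    wrong_rate: float = 0.0,
    mapq_model: str = "uniform",
    seed: int = 0,
) -> list[MappingRecord]:
    """Synthetic primary PAF records with a controlled error rate.

    Each read yields one primary record placed exactly on its truth
    interval, except that with probability ``wrong_rate`` it is displaced
    to a random locus that does not overlap the truth.  ``mapq_model``:

    * ``"uniform"`` — mapq drawn uniformly from 0..60, independent of
      correctness (the threshold-0 error rate estimates ``wrong_rate``);
    * ``"informative"`` — correct placements get high mapq (normal around
      55), wrong ones low mapq (normal around 8), clipped to 0..60, so
      error concentrates at low thresholds as with a real mapper.
    """
    if not 0.0 <= wrong_rate <= 1.0:
        raise ValueError(f"wrong_rate must be in [0, 1], got {wrong_rate}")
    if mapq_model not in ("uniform", "informative"):
        raise ValueError(f"unknown mapq model {mapq_model!r}")
    rng = np.random.default_rng(seed)
    names = sorted(target_lengths)
    records: list[MappingRecord] = []
    for truth in truths:
        o = truth.origin
        wrong = rng.random() < wrong_rate
        tname, tstart, tend = o.name, o.start, o.end
        if wrong:
            for _attempt in range(200):
                tname = names[rng.integers(0, len(names))]
                tlen = target_lengths[tname]
                span = min(o.length, tlen) or 1
                tstart = int(rng.integers(0, max(1, tlen - span + 1)))
                tend = min(tstart + span, tlen)
                candidate = GenomicInterval(tname, tstart, tend)
                if candidate.overlap(o) == 0:
                    break
            else:
                raise ValueError("could not place a non-overlapping wrong mapping")
        if mapq_model == "uniform":
            mapq = int(rng.integers(0, 61))
        else:
            center, spread = (8.0, 6.0) if wrong else (55.0, 6.0)
            mapq = int(np.clip(round(rng.normal(center, spread)), 0, 60))
        qlen = o.length
        records.append(
            MappingRecord(
                qname=truth.name, qlen=qlen, qstart=0, qend=qlen,
                strand=o.strand,
                tname=tname, tlen=int(target_lengths[tname]),
                tstart=tstart, tend=tend,
                nmatch=max(1, int(0.95 * qlen)), alnlen=max(1, qlen),
                mapq=mapq, primary=True,
            )
        )
    return records
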