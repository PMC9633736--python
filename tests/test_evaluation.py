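"""mapeval correctness, mapq-threshold curves, and MSR selection."""

import random

import numpy as np
import pytest

from seqreduce import (
    EvalCurve,
    GenomicInterval,
    ReadTruth,
    eval_curve,
    is_correct,
    percent_better,
    repeat_read_filter,
    respective_threshold,
    select_msrs,
    synth_mappings,
)
from seqreduce.evaluation import (
    FULL_THRESHOLDS,
    EvalPoint,
    read_curve_tsv,
    read_truth_tsv,
    truth_from_name,
    write_curve_tsv,
    write_truth_tsv,
)
from seqreduce.paf import MappingRecord


def _mapping(tname="chr", tstart=0, tend=100, mapq=60, qname="r0", primary=True):
    return MappingRecord(
        qname=qname, qlen=tend - tstart, qstart=0, qend=tend - tstart, strand="+",
        tname=tname, tlen=10_000, tstart=tstart, tend=tend,
        nmatch=1, alnlen=max(1, tend - tstart), mapq=mapq, primary=primary,
    )


def _truth(qname="r0", tname="chr", start=0, end=100):
    return ReadTruth(qname, GenomicInterval(tname, start, end))


# ---------------------------------------------------------------------------
# Correctness criterion

def test_is_correct_examples():
    assert is_correct(_mapping(), _truth())  # exact placement: I/U = 1
    # I = 5, U = 200: ratio 0.025 < 0.10
    assert not is_correct(_mapping(tstart=95, tend=200), _truth())
    assert not is_correct(_mapping(tname="other"), _truth())


def test_is_correct_matches_brute_force_interval_sets():
    rng = random.Random(23)
    for _ in range(10_000):
        a0 = rng.randint(0, 300)
        a1 = a0 + rng.randint(0, 200)
        b0 = rng.randint(0, 300)
        b1 = b0 + rng.randint(0, 200)
        m = _mapping(tstart=a0, tend=a1)
        t = _truth(start=b0, end=b1)
        sa, sb = set(range(a0, a1)), set(range(b0, b1))
        union = len(sa | sb)
        expected = union > 0 and len(sa & sb) / union >= 0.10
        assert is_correct(m, t) is expected


# ---------------------------------------------------------------------------
# Threshold curves

def test_perfect_mapping_gives_perfect_curve():
    truths = [_truth(qname=f"r{i}", start=i * 10, end=i * 10 + 100) for i in range(50)]
    mappings = [
        _mapping(qname=t.name, tstart=t.origin.start, tend=t.origin.end, mapq=60)
        for t in truths
    ]
    curve = eval_curve(mappings, truths)
    for p in curve.points:
        assert p.fraction_mapped == 1.0 and p.error_rate == 0.0


def test_no_mappings_yields_zero_curve_by_convention():
    curve = eval_curve([], [_truth(qname=f"r{i}") for i in range(10)])
    for p in curve.points:
        assert p.fraction_mapped == 0.0 and p.error_rate == 0.0


def test_unknown_read_name_is_an_error():
    with pytest.raises(ValueError, match="unknown read"):
        eval_curve([_mapping(qname="ghost")], [_truth(qname="r0")])


def test_secondary_alignments_are_ignored():
    truths = [_truth()]
    curve = eval_curve([_mapping(primary=False)], truths)
    assert curve.points[-1].fraction_mapped == 0.0


def test_wrong_rate_recovery_at_threshold_zero():
    """Injected wrong-placement probabilities are recovered at t = 0 within
    3 binomial standard deviations, for p in {0.01, 0.05, 0.2}."""
    n = 10_000
    truths = [
        _truth(qname=f"r{i}", tname="chr1", start=(7 * i) % 90_000, end=(7 * i) % 90_000 + 500)
        for i in range(n)
    ]
    lengths = {"chr1": 100_000, "chr2": 100_000}
    for p in (0.01, 0.05, 0.2):
        recs = synth_mappings(truths, lengths, wrong_rate=p, mapq_model="uniform", seed=77)
        curve = eval_curve(recs, truths, FULL_THRESHOLDS)
        sd = (p * (1 - p) / n) ** 0.5
        assert abs(curve.error_at(0) - p) <= 3 * sd
        assert curve.fraction_at(0) == 1.0


def test_curves_are_monotone_when_error_sits_at_low_mapq():
    n = 5_000
    truths = [_truth(qname=f"r{i}", start=i % 9_000, end=i % 9_000 + 400) for i in range(n)]
    recs = synth_mappings(truths, {"chr": 10_000}, wrong_rate=0.1, mapq_model="informative", seed=5)
    curve = eval_curve(recs, truths, FULL_THRESHOLDS)
    fracs = [p.fraction_mapped for p in curve.points]  # 60 -> 0
    errs = [p.error_rate for p in curve.points]
    assert all(a <= b for a, b in zip(fracs, fracs[1:]))  # fraction grows as t drops
    assert all(a <= b for a, b in zip(errs, errs[1:]))  # error grows as t drops


# ---------------------------------------------------------------------------
# Respective thresholds and selection

def _curve(frac_err_by_t):
    """Build a full-resolution curve from {threshold: (fraction, error)}."""
    points = tuple(
        EvalPoint(t, frac_err_by_t[t][0], frac_err_by_t[t][1], 0, 0)
        for t in sorted(frac_err_by_t, reverse=True)
    )
    return EvalCurve(points=points, total_reads=1000)


def _flat_curve(fraction, error):
    return _curve({t: (fraction, error) for t in range(61)})


def test_respective_threshold_scan():
    assert respective_threshold(_flat_curve(0.95, 0.001), 0.93, 0.002) == 60
    assert respective_threshold(_flat_curve(0.90, 0.01), 0.93, 0.002) is None
    # dominates only at t <= 50
    table = {t: ((0.95, 0.001) if t <= 50 else (0.92, 0.001)) for t in range(61)}
    assert respective_threshold(_curve(table), 0.93, 0.002) == 50


def test_respective_threshold_satisfies_both_strict_inequalities():
    rng = random.Random(31)
    for _ in range(100):
        table = {
            t: (rng.uniform(0.85, 1.0), rng.uniform(0.0, 0.01)) for t in range(61)
        }
        curve = _curve(table)
        rt = respective_threshold(curve, 0.93, 0.002)
        if rt is not None:
            assert curve.fraction_at(rt) > 0.93
            assert curve.error_at(rt) < 0.002


def test_percent_better_counts_thresholds_one_to_sixty():
    assert percent_better(_flat_curve(0.95, 0.001), 0.93, 0.002) == 1.0
    assert percent_better(_flat_curve(0.90, 0.01), 0.93, 0.002) == 0.0
    # better at exactly the 20 thresholds 41..60
    table = {t: ((0.95, 0.001) if t > 40 else (0.90, 0.01)) for t in range(61)}
    assert percent_better(_curve(table), 0.93, 0.002) == 20 / 60
    # ties lose: equal fraction is not "higher"
    assert percent_better(_flat_curve(0.93, 0.001), 0.93, 0.002) == 0.0


def test_selection_with_one_dominant_curve():
    hpc = _flat_curve(0.93, 0.002)
    curves = {f"ssr{i:03d}": _flat_curve(0.90 - i * 1e-4, 0.01) for i in range(40)}
    curves["ssr_best"] = _flat_curve(0.99, 0.0001)
    report = select_msrs(curves, hpc)
    assert report.union == ("ssr_best",)
    assert report.top_fraction == report.top_error == report.top_percent == ("ssr_best",)
    assert report.best_fraction == report.best_error == report.best_percent == "ssr_best"
    assert report.respective_thresholds["ssr_best"] == 60


def test_selection_when_nothing_beats_the_reference():
    hpc = _flat_curve(0.93, 0.002)
    curves = {f"ssr{i}": _flat_curve(0.93, 0.002) for i in range(5)}
    report = select_msrs(curves, hpc)
    assert report.union == ()
    assert all(rt is None for rt in report.respective_thresholds.values())


def test_selection_union_is_bounded_and_deterministic():
    rng = random.Random(41)
    hpc = _flat_curve(0.93, 0.002)
    curves = {}
    for i in range(200):
        f = rng.uniform(0.90, 0.99)
        e = rng.uniform(0.0, 0.004)
        curves[f"ssr{i:04d}"] = _flat_curve(f, e)
    r1 = select_msrs(curves, hpc)
    r2 = select_msrs(dict(reversed(list(curves.items()))), hpc)
    assert len(r1.union) <= 60
    assert r1.union == r2.union and r1.top_error == r2.top_error


# ---------------------------------------------------------------------------
# Repeat-region read filter

def test_repeat_read_filter_overlap_rule():
    repeats = [GenomicInterval("chr", 1000, 2000)]
    inside = ReadTruth("in", GenomicInterval("chr", 1100, 1500))
    forty_pct = ReadTruth("forty", GenomicInterval("chr", 600, 1400))  # 400/1000
    sixty_pct = ReadTruth("sixty", GenomicInterval("chr", 900, 1900))  # 900/1000 > 0.5
    other = ReadTruth("other", GenomicInterval("chr2", 1100, 1500))
    kept = repeat_read_filter([inside, forty_pct, sixty_pct, other], repeats)
    assert [t.name for t in kept] == ["in", "sixty"]
    assert repeat_read_filter([inside], []) == []


def test_repeat_filter_merges_overlapping_repeat_intervals():
    repeats = [GenomicInterval("chr", 0, 600), GenomicInterval("chr", 400, 1000)]
    read = ReadTruth("r", GenomicInterval("chr", 300, 900))  # 600/600 after merge
    assert repeat_read_filter([read], repeats) == [read]


# ---------------------------------------------------------------------------
# Truth and curve round trips

def test_truth_name_codec_and_tsv_round_trip(tmp_path):
    t = truth_from_name("r0001!chr2!150!900!-")
    assert t.origin == GenomicInterval("chr2", 150, 900, "-")
    with pytest.raises(ValueError):
        truth_from_name("plain_read_name")
    p = tmp_path / "truth.tsv"
    write_truth_tsv([t], p)
    assert read_truth_tsv(p) == [t]


def test_curve_tsv_round_trip(tmp_path):
    truths = [_truth(qname=f"r{i}") for i in range(20)]
    maps = [_mapping(qname=t.name, mapq=30 + (i % 3)) for i, t in enumerate(truths)]
    curve = eval_curve(maps, truths)
    p = tmp_path / "curve.tsv"
    write_curve_tsv(curve, p)
    back = read_curve_tsv(p)
    assert back == curve
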