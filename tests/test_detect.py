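"""Offset histograms, period estimation, region calling, pattern classes."""

import numpy as np
import pytest

from tandemkit.detect import (
    DetectParams,
    ReadPattern,
    TRRegion,
    call_tr_regions,
    classify_pattern,
    detect_read,
    estimate_period,
    offset_histogram,
)
from tandemkit.selfalign import seed_matches
from tandemkit.seqio import LongRead
from tandemkit.synth import SynthSpec, build_read, random_monomer

from conftest import random_dna


def self_ms(seq: str, word: int = 10):
    return seed_matches(seq, seq, word=word, both_strands=False,
                        query_id="s", target_id="s")


def test_offset_histogram_perfect_array(monomer120):
    hist = offset_histogram(self_ms(monomer120 * 8))
    # support at multiples of 120 decreases linearly: offset k*120 aligns
    # (8-k) copy pairs of 120 bp each
    for k in range(1, 8):
        assert hist[120 * k] == (8 - k) * 120
    assert 0 not in hist
    assert set(hist) == {120 * k for k in range(1, 8)}


def test_offset_histogram_short_period():
    hist = offset_histogram(self_ms("CCCTAAA" * 20, word=7))
    assert {7, 14, 21} <= set(hist)
    assert max(hist, key=hist.get) == 7


def test_offset_histogram_random_sequence_is_flat():
    hist = offset_histogram(self_ms(random_dna(np.random.default_rng(2), 1000)))
    assert all(v < 3 * 10 for v in hist.values())


def test_offset_histogram_rejects_non_self():
    ms = seed_matches("ACGTACGTACGT", "ACGTACGTACGT", query_id="a", target_id="b")
    with pytest.raises(ValueError):
        offset_histogram(ms)


def test_estimate_period_fundamental_not_harmonic(monomer120):
    hist = offset_histogram(self_ms(monomer120 * 8))
    assert estimate_period(hist) == pytest.approx(120.0)


def test_estimate_period_random_is_none():
    hist = offset_histogram(self_ms(random_dna(np.random.default_rng(3), 1000)))
    assert estimate_period(hist) is None
    assert estimate_period({}) is None


def test_estimate_period_noisy_recovery():
    ok = 0
    for seed in range(40):
        unit = [60, 120, 225, 385][seed % 4]
        read, _ = build_read(SynthSpec(seed=7000 + seed, unit_length=unit,
                                       copies=10, pattern=ReadPattern.FULL,
                                       read_len_target=6000))
        hist = offset_histogram(self_ms(read.sequence))
        p = estimate_period(hist)
        if p is not None and abs(p - unit) <= 0.10 * unit:
            ok += 1
    assert ok >= 38  # 95%


def test_call_tr_regions_partial_array(monomer120):
    rng = np.random.default_rng(4)
    seq = random_dna(rng, 2000) + monomer120 * 8 + random_dna(rng, 2000)
    read = LongRead("r", "r", seq)
    regions = call_tr_regions(read, self_ms(seq))
    good = [r for r in regions if not r.low_complexity]
    assert len(good) == 1
    r = good[0]
    truth = (2000, 2000 + 960)
    overlap = min(r.end, truth[1]) - max(r.start, truth[0])
    assert overlap >= 0.9 * 960
    assert r.period_bp == pytest.approx(120, rel=0.05)
    assert r.continuity == pytest.approx(1.0)
    assert abs(r.copy_estimate - (r.end - r.start) / r.period_bp) <= 1


def test_call_tr_regions_two_arrays_same_period(monomer120):
    rng = np.random.default_rng(5)
    seq = (random_dna(rng, 500) + monomer120 * 8 + random_dna(rng, 3000)
           + monomer120 * 8 + random_dna(rng, 500))
    read = LongRead("r", "r", seq)
    good = [r for r in call_tr_regions(read, self_ms(seq)) if not r.low_complexity]
    assert len(good) == 2
    assert good[0].period_bp == pytest.approx(good[1].period_bp, rel=0.05)


def test_poly_a_run_is_low_complexity():
    rng = np.random.default_rng(6)
    seq = random_dna(rng, 1000) + "A" * 1000 + random_dna(rng, 1000)
    read = LongRead("r", "r", seq)
    regions = call_tr_regions(read, self_ms(seq))
    assert regions and all(r.low_complexity for r in regions)
    assert classify_pattern(read, regions) is ReadPattern.NO_TR_LOW_COMPLEXITY


def region(start, end, period, low=False):
    copies = (end - start) / period
    return TRRegion(start, end, period, copies, int((copies - 1) * period), 1.0, low)


def test_classify_pattern_rules():
    read = LongRead("r", "r", "A" * 10000)
    assert classify_pattern(read, [region(200, 9800, 120)]) is ReadPattern.FULL
    assert classify_pattern(read, [region(1000, 5000, 120)]) is ReadPattern.PARTIAL
    two_close = [region(0, 3000, 120), region(6000, 9000, 121)]
    assert classify_pattern(read, two_close) is ReadPattern.INTERSPERSED
    two_far = [region(0, 3000, 120), region(6000, 9000, 225)]
    assert classify_pattern(read, two_far) is ReadPattern.COMBO
    # explicit family labels override the period heuristic
    assert classify_pattern(read, two_far, ["famA", "famA"]) is ReadPattern.INTERSPERSED
    assert classify_pattern(read, two_close, ["famA", "famB"]) is ReadPattern.COMBO
    assert classify_pattern(read, [region(0, 3000, 120, low=True)]) \
        is ReadPattern.NO_TR_LOW_COMPLEXITY


@pytest.mark.parametrize("pattern", list(ReadPattern))
def test_error_free_pattern_recovery(pattern):
    for i in range(5):
        unit = [60, 120, 225, 385][i % 4]
        spec = SynthSpec(seed=5000 + i, unit_length=unit, copies=10,
                         pattern=pattern, read_len_target=8000,
                         unit_length2=unit * 2 if pattern is ReadPattern.COMBO else None,
                         sub_rate=0, ins_rate=0, del_rate=0)
        read, truth = build_read(spec)
        _, got = detect_read(read)
        assert got is pattern


def test_continuity_error_free_is_one_and_decreases_with_noise():
    means = []
    for rate in [0.0, 0.05, 0.10, 0.20]:
        vals = []
        for seed in range(12):
            spec = SynthSpec(seed=8000 + seed, unit_length=120, copies=10,
                             pattern=ReadPattern.FULL, read_len_target=5000,
                             sub_rate=rate, ins_rate=0, del_rate=0)
            read, _ = build_read(spec)
            regions, _ = detect_read(read)
            good = [r for r in regions if not r.low_complexity]
            if good:
                vals.append(max(good, key=lambda r: r.support_bp).continuity)
        means.append(np.mean(vals))
    assert means[0] == pytest.approx(1.0, abs=1e-9)
    assert all(a >= b for a, b in zip(means, means[1:]))  # non-increasing


def test_detect_params_validation():
    with pytest.raises(ValueError):
        DetectParams(min_period=0)
    with pytest.raises(ValueError):
        DetectParams(full_coverage_frac=1.5)
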