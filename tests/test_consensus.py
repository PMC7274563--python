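"""Consensus derivation, array scoring, unit rounding and AT content."""

import edlib
import numpy as np
import pytest

from tandemkit.consensus import (
    TrfParams,
    at_content,
    derive_consensus,
    round_unit_length,
    segment_monomers,
)
from tandemkit.detect import ReadPattern, detect_read
from tandemkit.seqio import LongRead
from tandemkit.synth import SynthSpec, build_read, mutate, random_monomer


def rotation_distance(consensus: str, truth: str) -> int:
    """Edit distance of truth to the best rotation of the consensus."""
    return edlib.align(truth, consensus + consensus, mode="HW")["editDistance"]


def best_region(read):
    regions, _ = detect_read(read)
    good = [r for r in regions if not r.low_complexity]
    assert good, "no qualifying region"
    return max(good, key=lambda r: r.support_bp)


def test_perfect_array_recovers_monomer(monomer120, perfect_array_read):
    reg = best_region(perfect_array_read)
    u = derive_consensus(perfect_array_read, reg, reg.period_bp)
    assert u is not None
    assert u.period_refined == 120
    assert rotation_distance(u.consensus, monomer120) == 0
    assert u.copies == pytest.approx(8.0, abs=0.1)
    assert u.rounded_size == 120
    assert u.array_score == 2 * 8 * 120  # all bases match at +2 each


@pytest.mark.parametrize("unit", [50, 60, 120, 135, 225, 385, 600])
def test_error_free_period_exact(unit):
    mono = random_monomer(unit, 0.6, unit + 7)
    read = LongRead("r", "r", mono * max(8, 1200 // unit))
    reg = best_region(read)
    u = derive_consensus(read, reg, reg.period_bp)
    assert u is not None and u.period_refined == unit


def test_min_report_score_threshold():
    # total matched length 24 at match=2 scores 48 < 50 -> suppressed;
    # 25 matched bases score 50 -> reported
    read24 = LongRead("r", "r", "ACGGTCACGGTC" * 2)  # 2 x 12 = 24 bp
    reg = type("R", (), dict(start=0, end=24))
    u = derive_consensus(read24, reg, 12)
    assert u is None
    read25 = LongRead("r", "r", "ACGGT" * 5)  # 5 x 5 = 25 bp
    reg = type("R", (), dict(start=0, end=25))
    u = derive_consensus(read25, reg, 5)
    assert u is not None and u.array_score == 50


def test_score_monotone_exact_increment(monomer120):
    scores = []
    for m in (6, 7, 8):
        read = LongRead("r", "r", monomer120 * m)
        reg = type("R", (), dict(start=0, end=120 * m))
        scores.append(derive_consensus(read, reg, 120).array_score)
    assert scores[1] - scores[0] == 2 * 120
    assert scores[2] - scores[1] == 2 * 120


def test_region_shorter_than_two_periods():
    mono = random_monomer(120, 0.6, 77)
    read = LongRead("r", "r", mono + mono[:60])
    reg = type("R", (), dict(start=0, end=180))
    assert derive_consensus(read, reg, 120) is None


def test_rotation_invariance(monomer120):
    """Consensi from differently phased cuts of one array are rotations."""
    consensi = []
    for shift in (0, 37, 81):
        seq = (monomer120[shift:] + monomer120[:shift]) * 8
        read = LongRead("r", "r", seq)
        reg = type("R", (), dict(start=0, end=len(seq)))
        consensi.append(derive_consensus(read, reg, 120).consensus)
    for c in consensi[1:]:
        d = edlib.align(consensi[0], c + c, mode="HW")["editDistance"]
        assert d <= 0.05 * 120


def test_noisy_consensus_accuracy():
    """At ~10% composite error the consensus stays within 5% of truth."""
    ok = 0
    n = 30
    for seed in range(n):
        spec = SynthSpec(seed=seed, unit_length=120, copies=10,
                         pattern=ReadPattern.FULL, read_len_target=6000)
        read, _ = build_read(spec)
        truth = random_monomer(120, 0.60, (seed * 1_000_003 + 1) % (2**31 - 1))
        reg = best_region(read)
        u = derive_consensus(read, reg, reg.period_bp)
        if u is not None and rotation_distance(u.consensus, truth) <= 6:
            ok += 1
    assert ok >= 0.9 * n


def test_segment_monomers_tracks_drift(monomer120):
    noisy = mutate(monomer120 * 15, 0.04, 0.03, 0.03, 9)
    spans = segment_monomers(noisy, monomer120)
    assert 13 <= len(spans) <= 15
    for s, e in spans:
        assert abs((e - s) - 120) <= 18  # within 15% of the unit
    # spans are consecutive and non-overlapping
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert s2 >= e1


@pytest.mark.parametrize(
    "value,expected",
    [(118, 120), (122.4, 120), (223, 225), (52.5, 55), (60, 60)],
)
def test_round_unit_length(value, expected):
    assert round_unit_length(value) == expected
    with pytest.raises(ValueError):
        round_unit_length(0)


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ATAT", 100),
        ("GCGC", 0),
        ("TTAGTGCAATGTTATCTAGT", 70),  # a 20-mer with 14 A/T bases
        ("ACGTN", 50),  # N excluded from numerator and denominator
    ],
)
def test_at_content(seq, expected):
    assert at_content(seq) == expected


def test_trf_params_validation():
    with pytest.raises(ValueError):
        TrfParams(match=-1)
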