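"""Seeded benchmark experiments over the synthetic study conditions.

Each function regenerates its inputs from scratch with the given seed,
runs the relevant pipeline stages, and measures an aggregate quantity:
the copy-number threshold of the k-mer retention rule, period and pattern
recovery under ~10% composite read error, family-assignment accuracy and
background specificity against a six-family catalog, consensus accuracy,
screening enrichment, and the monotone behavior of the continuity and
within-read identity statistics.  The same functions back the acceptance
test suite and the standalone acceptance script.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import edlib
import numpy as np

from . import catalog as cat
from .consensus import derive_consensus
from .detect import ReadPattern, detect_read
from .divergence import MonomerSet, identity_analysis
from .kmer import ScreenParams, passes_ksift, screen_library
from .seqio import LongRead
from .synth import SynthSpec, _child_seed, build_library, build_read, mutate, random_monomer

STUDY_UNITS = (60, 120, 225, 385)
CATALOG_UNITS = (60, 120, 225, 335, 450, 600)
NOISE = dict(sub_rate=0.04, ins_rate=0.03, del_rate=0.03)  # ~10% composite
HALF_NOISE = dict(sub_rate=0.02, ins_rate=0.015, del_rate=0.015)  # ~5%


def _rng_seed(seed: int, salt: int) -> int:
    return int((seed * 7_654_321 + salt) % (2**31 - 1))


def min_copies_for_retention(seed: int, unit: int = 120) -> int:
    """Smallest copy number of an exact tandem array that passes the k-mer
    retention criterion, scanning m = 2..12 on reads padded to >= 5 kb."""
    mono = random_monomer(unit, 0.60, _rng_seed(seed, 1))
    rng = np.random.default_rng(_rng_seed(seed, 2))
    params = ScreenParams()
    for m in range(2, 13):
        flank_len = max(0, 5200 - m * unit)
        flank = "".join(rng.choice(list("ACGT"), size=flank_len))
        read = LongRead("r", "r", flank[: flank_len // 2] + mono * m
                        + flank[flank_len // 2 :])
        if passes_ksift(read, params):
            return m
    return 0


def _best_region(read: LongRead):
    regions, pattern = detect_read(read)
    good = [r for r in regions if not r.low_complexity]
    if not good:
        return None, pattern
    return max(good, key=lambda r: r.support_bp), pattern


def period_recovery(seed: int, n_reads: int = 200) -> float:
    """Fraction of noisy arrays (>= 8 copies) whose period is recovered
    within +-10%, over reads spanning the study unit lengths."""
    ok = 0
    for i in range(n_reads):
        unit = STUDY_UNITS[i % len(STUDY_UNITS)]
        pattern = (ReadPattern.FULL, ReadPattern.PARTIAL)[(i // 4) % 2]
        spec = SynthSpec(seed=_rng_seed(seed, 100 + i), unit_length=unit,
                         at_fraction=0.60, copies=10, pattern=pattern,
                         read_len_target=8000, **NOISE)
        read, _ = build_read(spec)
        region, _ = _best_region(read)
        if region is not None and abs(region.period_bp - unit) <= 0.10 * unit:
            ok += 1
    return ok / n_reads


def pattern_accuracy(seed: int, noisy: bool, n_reads: int = 100) -> float:
    """Five-way pattern classification accuracy on generated reads."""
    patterns = list(ReadPattern)
    rates = NOISE if noisy else dict(sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
    ok = 0
    for i in range(n_reads):
        pattern = patterns[i % 5]
        unit = STUDY_UNITS[i % 4]
        spec = SynthSpec(
            seed=_rng_seed(seed, 2000 + i), unit_length=unit, at_fraction=0.60,
            copies=10, pattern=pattern, read_len_target=8000,
            unit_length2=unit * 2 if pattern is ReadPattern.COMBO else None,
            **rates,
        )
        read, _ = build_read(spec)
        _, got = detect_read(read)
        if got is pattern:
            ok += 1
    return ok / n_reads


def build_study_catalog(seed: int) -> cat.PolySeq:
    """Six-family polySeq over units 60-600 bp with seeded consensi."""
    return cat.build_polyseq(
        [
            dict(name=cat.family_name(u),
                 consensus=random_monomer(u, 0.60, _rng_seed(seed, 3000 + u)))
            for u in CATALOG_UNITS
        ]
    )


def family_assignment_accuracy(
    seed: int, n_reads: int = 300
) -> Tuple[float, cat.PolySeq]:
    """Top-assignment accuracy for reads simulated from catalog families
    at ~5% error."""
    ps = build_study_catalog(seed)
    ok = 0
    for i in range(n_reads):
        fam = ps.families[i % len(ps.families)]
        copies = max(8, 6000 // fam.unit_length_bp)
        noisy = mutate(fam.consensus * copies, seed=_rng_seed(seed, 4000 + i),
                       **HALF_NOISE)
        read = LongRead(f"q{i}", f"q{i}", noisy)
        regions, _ = detect_read(read)
        asg = cat.assign_read(read, regions, ps)
        if asg and asg[0].family_name == fam.name:
            ok += 1
    return ok / n_reads, ps


def background_false_assignments(
    seed: int, ps: Optional[cat.PolySeq] = None, n_reads: int = 3000
) -> int:
    """Number of catalog-family assignments earned by random background reads
    (the specificity of the catalog: the expected count is zero)."""
    ps = ps or build_study_catalog(seed)
    reads, _ = build_library([], n_background=n_reads, seed=_rng_seed(seed, 5000))
    false = 0
    for read in reads:
        regions, _ = detect_read(read)
        for a in cat.assign_read(read, regions, ps):
            if a.family_name != cat.NEW_FAMILY:
                false += 1
    return false


def enrichment_benchmark(
    seed: int, n_background: int = 1000, n_tr: int = 10
) -> Tuple[float, float]:
    """(measured enrichment factor, 1/prevalence) for a library screening."""
    mono = random_monomer(120, 0.60, _rng_seed(seed, 6000))
    specs = [
        SynthSpec(seed=_rng_seed(seed, 6100 + i), monomer=mono, copies=10,
                  pattern=ReadPattern.FULL, read_len_target=7000, **NOISE)
        for i in range(n_tr)
    ]
    reads, _ = build_library(specs, n_background=n_background,
                             seed=_rng_seed(seed, 6200))
    _, stats = screen_library(reads)
    prevalence = n_tr / (n_tr + n_background)
    return stats.enrichment_factor, 1.0 / prevalence


def consensus_accuracy(seed: int, n_reads: int = 100, unit: int = 120) -> float:
    """Fraction of noisy reads whose derived consensus lies within edit
    distance <= 5% of the unit from the generating monomer (rotation-aware)."""
    ok = 0
    budget = int(0.05 * unit)
    for i in range(n_reads):
        child = _rng_seed(seed, 7000 + i)
        spec = SynthSpec(seed=child, unit_length=unit, at_fraction=0.60,
                         copies=10, pattern=ReadPattern.FULL,
                         read_len_target=6000, **NOISE)
        read, _ = build_read(spec)
        truth = random_monomer(unit, 0.60, _child_seed(child, 1))
        region, _ = _best_region(read)
        if region is None:
            continue
        unit_cons = derive_consensus(read, region, region.period_bp)
        if unit_cons is None:
            continue
        d = edlib.align(truth, unit_cons.consensus + unit_cons.consensus,
                        mode="HW")["editDistance"]
        if d <= budget:
            ok += 1
    return ok / n_reads


def score_increment_per_copy(seed: int, unit: int = 120) -> int:
    """Array-score gain from appending one exact monomer copy."""
    mono = random_monomer(unit, 0.60, _rng_seed(seed, 8000))
    scores = []
    for m in (8, 9):
        read = LongRead("r", "r", mono * m)
        region, _ = _best_region(read)
        scores.append(derive_consensus(read, region, region.period_bp).array_score)
    return scores[1] - scores[0]


def continuity_by_rate(
    seed: int, rates=(0.0, 0.05, 0.10, 0.20), n_reads: int = 50
) -> List[float]:
    """Mean continuity of full-read arrays at increasing substitution rates."""
    means = []
    for j, rate in enumerate(rates):
        vals = []
        for i in range(n_reads):
            spec = SynthSpec(seed=_rng_seed(seed, 9000 + 100 * j + i),
                             unit_length=120, at_fraction=0.60, copies=10,
                             pattern=ReadPattern.FULL, read_len_target=5000,
                             sub_rate=rate, ins_rate=0.0, del_rate=0.0)
            read, _ = build_read(spec)
            region, _ = _best_region(read)
            if region is not None:
                vals.append(region.continuity)
        means.append(float(np.mean(vals)) if vals else 0.0)
    return means


def within_read_identity_by_rate(
    seed: int, rates=(0.0, 0.1, 0.2, 0.3), n_sets: int = 30, n_monomers: int = 5
) -> List[float]:
    """Mean within-read monomer identity at increasing mutation rates."""
    mono = random_monomer(120, 0.60, _rng_seed(seed, 9500))
    means = []
    for j, rate in enumerate(rates):
        vals = []
        for i in range(n_sets):
            monomers = [
                mutate(mono, rate, 0.0, 0.0, _rng_seed(seed, 9600 + 97 * j + 7 * i + k))
                for k in range(n_monomers)
            ]
            _, rl = identity_analysis([MonomerSet("x", monomers, [0] * n_monomers)])
            vals.append(float(rl.iloc[0, 0]))
        means.append(float(np.mean(vals)))
    return means
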