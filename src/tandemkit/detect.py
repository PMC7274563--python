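"""Tandem-repeat region calling and read-level pattern classification.

From a self-alignment MatchSet, the perpendicular offsets (t_start -
q_start) of forward off-diagonal matches form a histogram whose fundamental
peak is the repeat unit length: copies i and i+1 of a unit of length p match
at offset p, copies i and i+2 at 2p, and so on.  Period estimation picks the
smallest strong offset whose harmonic series explains at least half the
off-diagonal support, which rejects harmonics (2p, 3p) in favor of the
fundamental and tolerates +-10% offset jitter from indel error.

Regions are the merged read-axis projections of off-diagonal matches.  Each
region carries a continuity index in [0,1]: off-diagonal matched bases
relative to the (copies-1) x period that a perfect array would align,
clamped to 1.  Continuity quantifies how unbroken the parallel diagonals
are, a proxy for within-array homogeneity.

Reads are classified into five patterns: NO_TR_LOW_COMPLEXITY (nothing but
microsatellite/homopolymer or no repeat at all), FULL (one array occupying
essentially the whole read), PARTIAL (one array, part of the read),
INTERSPERSED (multiple arrays of one family), COMBO (arrays of different
families in one read).
"""

from __future__ import annotations

import enum
import numpy as np
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .selfalign import MatchSet, SeedMatch, seed_matches
from .seqio import LongRead


class ReadPattern(str, enum.Enum):
    NO_TR_LOW_COMPLEXITY = "NO_TR_LOW_COMPLEXITY"
    FULL = "FULL"
    PARTIAL = "PARTIAL"
    INTERSPERSED = "INTERSPERSED"
    COMBO = "COMBO"


@dataclass
class DetectParams:
    min_period: int = 50  # below this the region is flagged low-complexity
    max_period: int = 1000
    min_copies: float = 3.0
    full_coverage_frac: float = 0.90
    merge_gap_bp: int = 500
    low_complexity_unit_max: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.min_period <= self.max_period):
            raise ValueError("need 0 < min_period <= max_period")
        if not (0 < self.full_coverage_frac <= 1):
            raise ValueError("full_coverage_frac must be in (0, 1]")


@dataclass
class TRRegion:
    """A called tandem-repeat interval on a read (0-based half-open)."""

    start: int
    end: int
    period_bp: float
    copy_estimate: float
    support_bp: int
    continuity: float
    low_complexity: bool = False


def offset_histogram(ms: MatchSet, matches: Optional[Sequence[SeedMatch]] = None) -> Dict[int, int]:
    """Support (matched bp) per off-diagonal offset of a self-alignment.

    Only forward matches with t_start > q_start contribute; the main
    diagonal (offset 0) is excluded.  Mirror matches below the diagonal are
    therefore not double-counted.
    """
    if not ms.is_self:
        raise ValueError("offset_histogram requires a self-alignment MatchSet")
    hist: Dict[int, int] = {}
    for m in matches if matches is not None else ms.matches:
        if m.strand == "+" and m.t_start > m.q_start:
            off = m.t_start - m.q_start
            hist[off] = hist.get(off, 0) + m.length
    return hist


def estimate_period(
    hist: Dict[int, int],
    params: DetectParams | None = None,
    word: int = 10,
    jitter_frac: float = 0.10,
) -> Optional[float]:
    """Fundamental period from an offset histogram, or None.

    Candidate fundamentals are offsets with support within a factor 0.5 of
    the maximum bin; the smallest candidate whose multiples (each +-
    ``jitter_frac`` x f) jointly hold >= 50% of the total support wins, so
    harmonics are rejected in favor of the fundamental.  Returns None when
    total off-diagonal support < min_copies x word.  The returned period is
    the support-weighted mean of the offsets in the fundamental's first
    harmonic band (absorbs indel jitter).
    """
    params = params or DetectParams()
    if not hist:
        return None
    total = sum(hist.values())
    if total < params.min_copies * word:
        return None
    max_support = max(hist.values())
    candidates = sorted(o for o, s in hist.items() if s >= 0.5 * max_support)
    items = list(hist.items())
    for f in candidates:
        covered = 0
        for o, s in items:
            k = round(o / f)
            # jitter tolerance scales with the multiple: indel drift accumulates
            if k >= 1 and abs(o - k * f) <= max(jitter_frac * k * f, 0.5):
                covered += s
        if covered >= 0.5 * total:
            tol = max(jitter_frac * f, 0.5)
            band = [(o, s) for o, s in items if abs(o - f) <= tol]
            num = sum(o * s for o, s in band)
            den = sum(s for o, s in band)
            return num / den
    return None


def _offset_supported(
    matches: List[SeedMatch], word: int, min_support_factor: int = 3
) -> List[SeedMatch]:
    """Drop matches whose offset neighborhood lacks corroboration.

    Matches of a true array share (near-)common offsets — the unit length
    and its multiples — while chance word matches sit at isolated offsets.
    A match is kept iff the total matched length at offsets within
    +-max(2 x word, 5% of offset) of its own reaches
    ``min_support_factor x word``.  This removes the scattered chance
    matches that would otherwise chain distant regions together during
    interval merging.
    """
    if not matches:
        return matches
    pairs = sorted((m.t_start - m.q_start, m.length) for m in matches)
    offsets = [p[0] for p in pairs]
    lengths = [p[1] for p in pairs]
    import bisect

    kept: List[SeedMatch] = []
    for m in matches:
        o = m.t_start - m.q_start
        tol = max(2 * word, 0.05 * o)
        lo = bisect.bisect_left(offsets, o - tol)
        hi = bisect.bisect_right(offsets, o + tol)
        if sum(lengths[lo:hi]) >= min_support_factor * word:
            kept.append(m)
    return kept


def _merge_intervals(
    intervals: List[Tuple[int, int]], merge_gap_bp: int
) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s - merged[-1][1] < merge_gap_bp:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def call_tr_regions(
    read: LongRead, ms: MatchSet, params: DetectParams | None = None
) -> List[TRRegion]:
    """Call tandem-repeat regions on a read from its self-alignment.

    Each forward off-diagonal match leaves two footprints on the read axis,
    [q_start, q_start + length) and [t_start, t_start + length); footprints
    closer than ``merge_gap_bp`` are merged.  (Projecting the full
    [q_start, t_start + length) span instead would let a single match
    between two distant arrays of one family — or a chance word match in
    random sequence — bridge unrelated regions into one.)  A local period
    is estimated from the offset histogram of the matches lying wholly
    inside each merged region, so between-array matches contribute to no
    region's period.  Regions whose period is below
    ``min_period`` (or whose unit is a microsatellite-scale
    ``low_complexity_unit_max``) or whose copy estimate is below
    ``min_copies`` are flagged low-complexity; regions where no period can
    be estimated are likewise flagged.
    """
    params = params or DetectParams()
    off = [m for m in ms.matches if m.strand == "+" and m.t_start > m.q_start]
    off = _offset_supported(off, ms.word)
    if not off:
        return []
    # Footprint coverage depth >= 2 delimits repeat-dense sequence: every
    # base of a true array is covered by footprints of several copy pairs,
    # while a chance match covers its footprints exactly once.
    cov = np.zeros(read.length + 1, dtype=np.int32)
    for m in off:
        cov[m.q_start] += 1
        cov[min(m.q_start + m.length, read.length)] -= 1
        cov[m.t_start] += 1
        cov[min(m.t_start + m.length, read.length)] -= 1
    depth = np.cumsum(cov[:-1])
    dense = depth >= 2
    intervals = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], dense.astype(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):
        intervals.append((int(s), int(e)))
    merged = _merge_intervals(intervals, params.merge_gap_bp)
    regions: List[TRRegion] = []
    for start, end in merged:
        inside = [
            m for m in off if m.q_start >= start and m.t_start + m.length <= end
        ]
        support = sum(m.length for m in inside)
        hist = offset_histogram(ms, inside)
        period = estimate_period(hist, params, word=ms.word)
        if period is None:
            # no coherent period: keep as a low-complexity/unstructured block
            fallback = max(hist, key=hist.get) if hist else 1
            regions.append(
                TRRegion(start, end, float(fallback), (end - start) / fallback,
                         support, 0.0, low_complexity=True)
            )
            continue
        copies = (end - start) / period
        denom = (copies - 1.0) * period
        continuity = min(1.0, support / denom) if denom > 0 else 0.0
        low = (
            period < params.min_period
            or period <= params.low_complexity_unit_max
            or copies < params.min_copies
            # weakly supported periodicity (chance or degenerate matches)
            or support / period < params.min_copies
        )
        regions.append(TRRegion(start, end, period, copies, support, continuity, low))
    return regions


def classify_pattern(
    read: LongRead,
    regions: Sequence[TRRegion],
    family_labels: Optional[Sequence[Optional[str]]] = None,
    params: DetectParams | None = None,
) -> ReadPattern:
    """Five-way pattern classification of a read from its called regions.

    With unknown family labels, two regions are treated as one family when
    their periods agree within 10%.
    """
    params = params or DetectParams()
    keep = [
        (r, family_labels[i] if family_labels else None)
        for i, r in enumerate(regions)
        if not r.low_complexity
    ]
    if not keep:
        return ReadPattern.NO_TR_LOW_COMPLEXITY
    if len(keep) >= 2:
        labels = [lab for _, lab in keep]
        if all(lab is not None for lab in labels):
            distinct = len(set(labels)) > 1
        else:
            periods = [r.period_bp for r, _ in keep]
            distinct = (max(periods) - min(periods)) > 0.10 * min(periods)
        return ReadPattern.COMBO if distinct else ReadPattern.INTERSPERSED
    region = keep[0][0]
    if (region.end - region.start) >= params.full_coverage_frac * read.length:
        return ReadPattern.FULL
    return ReadPattern.PARTIAL


def detect_read(
    read: LongRead, params: DetectParams | None = None, word: int = 10
) -> Tuple[List[TRRegion], ReadPattern]:
    """Convenience: self-align a read, call regions, classify its pattern."""
    ms = seed_matches(
        read.sequence, read.sequence, word=word, both_strands=False,
        query_id=read.read_id, target_id=read.read_id,
    )
    regions = call_tr_regions(read, ms, params)
    return regions, classify_pattern(read, regions, params=params)
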