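"""k-mer rank filter for tandem-repeat-bearing reads.

A read containing a tandem array of a unit >= k bp carries every one of the
unit's k-mers once per copy, so the high end of its per-read k-mer abundance
spectrum is lifted to roughly the copy number.  The retention criterion
("ksift"): a read is kept iff its ``rank``-th most abundant ``k``-mer occurs
at least ``min_count`` times.  With the defaults (k = 12, rank = 5,
min_count = 8) this keeps reads with >= 8 copies of a repeat unit while
random sequence of any realistic read length stays far below the threshold,
giving roughly thousand-fold enrichment on a whole-library screen.

k-mers are counted on the given strand only, with no canonical collapsing:
a tandem array lies on one strand of one molecule and the published
threshold is calibrated to raw window counts.  The multiset of counts is
strand-symmetric, so the rank statistic is identical for a read and its
reverse complement even though the keys differ.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

from .seqio import LongRead


@dataclass
class KmerCountProfile:
    read_id: str
    k: int
    counts: Dict[str, int]
    n_valid_windows: int


@dataclass
class ScreenParams:
    """Retention rule parameters; all strictly positive."""

    k: int = 12
    rank: int = 5
    min_count: int = 8
    min_read_len: int = 5000

    def __post_init__(self) -> None:
        if min(self.k, self.rank, self.min_count, self.min_read_len) < 1:
            raise ValueError("all ScreenParams fields must be strictly positive")


@dataclass
class ScreenStats:
    n_input: int
    n_retained: int
    enrichment_factor: float


def count_kmers(read: LongRead, k: int = 12) -> KmerCountProfile:
    """Count every length-*k* window on the read's given strand.

    Windows containing N are skipped entirely and excluded from
    ``n_valid_windows``.  A read shorter than *k* yields an empty profile.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    # Splitting on N drops exactly the windows that overlap an N.
    for segment in read.sequence.split("N"):
        for i in range(len(segment) - k + 1):
            counts[segment[i : i + k]] += 1
    return KmerCountProfile(read.read_id, k, dict(counts), sum(counts.values()))


def rank_count(profile: KmerCountProfile, rank: int = 5) -> int:
    """The *rank*-th order statistic of the count spectrum (non-increasing).

    Equal count values occupy consecutive ranks.  Returns 0 when the profile
    has fewer than *rank* distinct k-mers.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if len(profile.counts) < rank:
        return 0
    vals = sorted(profile.counts.values(), reverse=True)
    return vals[rank - 1]


def passes_ksift(read: LongRead, params: ScreenParams | None = None) -> bool:
    """True iff the read meets both the length and the k-mer rank criterion."""
    params = params or ScreenParams()
    if read.length < params.min_read_len:
        return False
    profile = count_kmers(read, params.k)
    return rank_count(profile, params.rank) >= params.min_count


def screen_library(
    reads: Iterable[LongRead], params: ScreenParams | None = None
) -> Tuple[List[LongRead], ScreenStats]:
    """Apply the retention criterion to a library, preserving order.

    ``enrichment_factor = n_input / max(n_retained, 1)``: on a library where
    a fraction p of reads carry a qualifying array, enrichment ~= 1/p.
    """
    params = params or ScreenParams()
    reads = list(reads)
    retained = [r for r in reads if passes_ksift(r, params)]
    stats = ScreenStats(
        n_input=len(reads),
        n_retained=len(retained),
        enrichment_factor=len(reads) / max(len(retained), 1),
    )
    return retained, stats
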