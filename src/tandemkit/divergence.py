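"""Monomer-level divergence within and between reads of one family.

For each read carrying an array, a block of ``n`` (default 11) consecutive
*internal* monomers (the first and last array copies are excluded as
potentially truncated) is extracted at consensus phase; among all candidate
windows the one whose monomers agree best with the consensus is taken.
Percent identity between monomers is computed from an end-to-end global
alignment with unit scores, with gap columns counted in the denominator
(the conservative reading of Clustal-style percent identity; a
matched-columns denominator is available via ``denominator="aligned"``).

The read-level matrix averages monomer pairs: off-diagonal cell (i, j) is
the mean of the n x n cross-read pairs; the diagonal cell is the mean of
the n(n-1)/2 unordered within-read pairs, self-pairs excluded (including
them would inflate within-read similarity).  The heat map uses a two-color
black (40) to yellow (70) ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from .consensus import ConsensusUnit, segment_monomers
from .seqio import LongRead


@dataclass
class MonomerSet:
    read_id: str
    monomers: List[str]
    source_offsets: List[int]


def extract_internal_monomers(
    read: LongRead, unit: ConsensusUnit, n: int = 11
) -> MonomerSet:
    """Extract *n* consecutive internal monomers from a read's array.

    Raises ValueError (naming the deficit) when the array holds fewer than
    n + 2 copies.
    """
    region_seq = read.sequence[unit.region.start : unit.region.end]
    spans = segment_monomers(region_seq, unit.consensus)
    internal = spans[1:-1]
    if len(internal) < n:
        raise ValueError(
            f"read {read.read_id}: need {n} internal monomers plus flanking "
            f"copies, found only {len(internal)} internal of {len(spans)} total"
        )
    # pick the window of n consecutive internal monomers closest to consensus
    dists = [
        edlib.align(region_seq[s:e], unit.consensus, mode="NW")["editDistance"]
        for s, e in internal
    ]
    best_i, best_d = 0, float("inf")
    for i in range(len(internal) - n + 1):
        d = sum(dists[i : i + n])
        if d < best_d:
            best_d, best_i = d, i
    chosen = internal[best_i : best_i + n]
    return MonomerSet(
        read_id=read.read_id,
        monomers=[region_seq[s:e] for s, e in chosen],
        source_offsets=[unit.region.start + s for s, _ in chosen],
    )


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def pairwise_identity(a: str, b: str, denominator: str = "columns") -> float:
    """Percent identity of an end-to-end global alignment with unit scores.

    ``denominator="columns"`` counts all alignment columns including gaps;
    ``"aligned"`` counts only non-gap columns.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    denom = columns if denominator == "columns" else counts.identities + counts.mismatches
    if denom == 0:
        return 0.0
    return 100.0 * counts.identities / denom


def identity_analysis(
    sets: Sequence[MonomerSet], denominator: str = "columns"
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Monomer-level and read-level averaged percent-identity matrices.

    The monomer matrix covers all monomers of all sets (labels
    ``<read>.<index>``).  The read matrix averages cross pairs off the
    diagonal and within-read unordered pairs (self-pairs excluded) on it.
    """
    if not sets:
        raise ValueError("need at least one MonomerSet")
    labels: List[str] = []
    seqs: List[str] = []
    owner: List[int] = []
    for si, s in enumerate(sets):
        for mi, m in enumerate(s.monomers):
            labels.append(f"{s.read_id}.{mi}")
            seqs.append(m)
            owner.append(si)
    n = len(seqs)
    mono = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = pairwise_identity(seqs[i], seqs[j], denominator)
            mono[i, j] = mono[j, i] = v
    mono_df = pd.DataFrame(mono, index=labels, columns=labels)
    read_ids = [s.read_id for s in sets]
    owner_arr = np.asarray(owner)
    k = len(sets)
    read_mat = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            rows = owner_arr == i
            cols = owner_arr == j
            sub = mono[np.ix_(rows, cols)]
            if i == j:
                iu = np.triu_indices(sub.shape[0], k=1)
                read_mat[i, j] = float(sub[iu].mean()) if iu[0].size else 100.0
            else:
                read_mat[i, j] = float(sub.mean())
    read_df = pd.DataFrame(read_mat, index=read_ids, columns=read_ids)
    return mono_df, read_df


def export_heatmap(
    matrix: pd.DataFrame, path: str | Path, vmin: float = 40.0, vmax: float = 70.0
) -> Path:
    """Two-color heat map of an identity matrix, black (vmin) to yellow (vmax)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("black_yellow", ["black", "yellow"])
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(matrix)),) * 2)
    im = ax.imshow(matrix.values, cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
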