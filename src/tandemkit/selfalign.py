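"""Exact-word seed matching and dot-plot rendering.

A dot plot of a sequence against itself shows tandem repeats as parallel
diagonals: every pair of repeat copies produces an off-main-diagonal stretch
of identity whose perpendicular offset equals a multiple of the unit length.
Matches are found by exact-word seeding (default word 10): every maximal
exact match of length >= word is reported once, with overlapping word hits
on one diagonal merged.  At ~10% read error, word-10 exact seeds still tile
true repeat copies densely enough for period estimation downstream.

Coordinates are 0-based, half-open throughout.  For a minus-strand match the
target start is given in forward target coordinates (start of the window
whose reverse complement equals the query window).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

from PIL import Image, ImageDraw

from ._dna import revcomp

PLUS_COLOR = (0, 140, 0)  # forward matches
MINUS_COLOR = (140, 0, 140)  # reverse-complement matches
BACKGROUND = (255, 255, 255)


@dataclass(frozen=True)
class SeedMatch:
    """A maximal exact match between two sequences (0-based, half-open)."""

    q_start: int
    t_start: int
    length: int
    strand: str  # '+' or '-'


@dataclass
class MatchSet:
    query_id: str
    target_id: str
    word: int
    both_strands: bool
    matches: List[SeedMatch] = field(default_factory=list)

    @property
    def is_self(self) -> bool:
        return self.query_id == self.target_id


def _plus_matches(seq_a: str, seq_b: str, word: int) -> List[SeedMatch]:
    """Maximal forward exact matches of length >= word (diagonal run merge)."""
    index: Dict[str, List[int]] = defaultdict(list)
    for t in range(len(seq_b) - word + 1):
        w = seq_b[t : t + word]
        if "N" not in w:
            index[w].append(t)
    # diagonal (t - q) -> sorted query start positions of word hits
    diagonals: Dict[int, List[int]] = defaultdict(list)
    for q in range(len(seq_a) - word + 1):
        w = seq_a[q : q + word]
        if "N" in w:
            continue
        for t in index.get(w, ()):
            diagonals[t - q].append(q)
    matches: List[SeedMatch] = []
    for d, qs in diagonals.items():
        run_start = qs[0]
        prev = qs[0]
        for q in qs[1:]:
            if q == prev + 1:
                prev = q
                continue
            matches.append(SeedMatch(run_start, run_start + d, prev - run_start + word, "+"))
            run_start = prev = q
        matches.append(SeedMatch(run_start, run_start + d, prev - run_start + word, "+"))
    matches.sort(key=lambda m: (m.q_start, m.t_start))
    return matches


def seed_matches(
    seq_a: str,
    seq_b: str,
    word: int = 10,
    both_strands: bool = True,
    query_id: str = "A",
    target_id: str = "B",
) -> MatchSet:
    """All maximal exact word matches between *seq_a* and *seq_b*.

    With ``both_strands`` the reverse-complement matches are reported too.
    A self-alignment (identical sequences) reports the main diagonal as one
    full-length match and every off-diagonal match together with its mirror.
    Sequences shorter than *word* yield an empty MatchSet.
    """
    if word < 4:
        raise ValueError("word must be >= 4")
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    ms = MatchSet(query_id, target_id, word, both_strands)
    if len(seq_a) < word or len(seq_b) < word:
        return ms
    ms.matches.extend(_plus_matches(seq_a, seq_b, word))
    if both_strands:
        rc = revcomp(seq_b)
        for m in _plus_matches(seq_a, rc, word):
            t_fwd = len(seq_b) - m.t_start - m.length
            ms.matches.append(SeedMatch(m.q_start, t_fwd, m.length, "-"))
    return ms


def render_dotplot(
    ms: MatchSet,
    len_a: int,
    len_b: int,
    path: str | Path,
    max_px: int = 1000,
) -> Path:
    """Render a MatchSet as a PNG dot plot.

    x-axis = sequence A position, y-axis = sequence B position, origin
    top-left.  Forward matches are drawn in green, reverse-complement in
    purple.  The scale factor is ``min(1, max_px / max(len_a, len_b))``
    pixels per bp; output bytes are deterministic for fixed input and scale.
    """
    if len_a <= 0 or len_b <= 0:
        raise ValueError("axes must have positive length")
    scale = min(1.0, max_px / max(len_a, len_b))
    w = max(1, round(len_a * scale))
    h = max(1, round(len_b * scale))
    img = Image.new("RGB", (w, h), BACKGROUND)
    draw = ImageDraw.Draw(img)
    for m in ms.matches:
        x0 = m.q_start * scale
        x1 = (m.q_start + m.length) * scale
        if m.strand == "+":
            y0 = m.t_start * scale
            y1 = (m.t_start + m.length) * scale
            color = PLUS_COLOR
        else:
            y0 = (m.t_start + m.length) * scale
            y1 = m.t_start * scale
            color = MINUS_COLOR
        draw.line([(x0, y0), (x1, y1)], fill=color, width=1)
    path = Path(path)
    img.save(path, format="PNG")
    return path


def matchset_table(ms: MatchSet):
    """SeedMatch rows as a pandas DataFrame (q_start, t_start, length, strand)."""
    import pandas as pd

    return pd.DataFrame(
        [(m.q_start, m.t_start, m.length, m.strand) for m in ms.matches],
        columns=["q_start", "t_start", "length", "strand"],
    )
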