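"""Conserved-window FISH oligo probe design from per-read consensi.

Per-read consensi of one family are cyclic rotations of each other (monomer
phase is arbitrary), so each is first rotated to best word-seed agreement
with the first consensus, then all are merged into a center-star multiple
alignment (every sequence pairwise-aligned to the first, merged on center
coordinates).  Probe selection slides a fixed-length window (default 22
columns; real oligo probes run 18-30 nt) across the alignment and takes the
window with the highest mean column conservation, leftmost on ties; the
probe sequence is the modal base of each window column with gap columns
dropped.  Probe rows are emitted in the conventional synthesis layout:
name, "5'-F-" + sequence, comma-joined fluorophore channel codes (F = FITC,
R = TRITC, Y = Cy5).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from .consensus import at_content
from .selfalign import seed_matches

FLUOR_CODES = ("F", "R", "Y")


@dataclass
class ProbeCandidate:
    name: str
    sequence: str
    msa_start: int
    conservation: float
    at_percent: int
    fluor_codes: Tuple[str, ...] = ()


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -1


def rotate_to_reference(seq: str, reference: str, word: int = 10) -> str:
    """Cyclic rotation of *seq* maximizing exact word-seed overlap with
    *reference*; returns *seq* unchanged when no seed is found."""
    if len(seq) < word:
        return seq
    ms = seed_matches(seq + seq, reference, word=word, both_strands=False)
    votes: Dict[int, int] = {}
    for m in ms.matches:
        r = (m.q_start - m.t_start) % len(seq)
        votes[r] = votes.get(r, 0) + m.length
    if not votes:
        return seq
    r = max(sorted(votes), key=lambda k: votes[k])
    return seq[r:] + seq[:r]


def align_consensi(consensi: Sequence[str], rotate: bool = True) -> List[str]:
    """Center-star multiple alignment of same-family consensi.

    The first sequence is the star center; every other sequence is rotated
    to it (cyclic phase normalization) and pairwise-aligned; alignments are
    merged on center coordinates.  Returns equal-length gapped rows; the
    column count is >= the longest input.
    """
    if len(consensi) < 2:
        raise ValueError("need at least 2 consensi to align")
    center = consensi[0]
    others = [
        rotate_to_reference(s, center) if rotate else s for s in consensi[1:]
    ]
    lc = len(center)
    # per sequence: inserted chars before each center position, aligned char per position
    parsed: List[Tuple[Dict[int, str], List[str]]] = []
    for s in others:
        aln = _aligner.align(center, s)[0]
        crow, srow = str(aln[0]), str(aln[1])
        ins: Dict[int, str] = {}
        aligned: List[str] = []
        p = 0
        for cc, sc in zip(crow, srow):
            if cc == "-":
                ins[p] = ins.get(p, "") + sc
            else:
                aligned.append(sc)
                p += 1
        parsed.append((ins, aligned))
    ins_max = {
        p: max((len(ins.get(p, "")) for ins, _ in parsed), default=0)
        for p in range(lc + 1)
    }
    rows: List[str] = []
    center_row = "".join(
        "-" * ins_max[p] + center[p] for p in range(lc)
    ) + "-" * ins_max[lc]
    rows.append(center_row)
    for ins, aligned in parsed:
        parts = []
        for p in range(lc):
            gap_block = ins.get(p, "")
            parts.append(gap_block.ljust(ins_max[p], "-") + aligned[p])
        parts.append(ins.get(lc, "").ljust(ins_max[lc], "-"))
        rows.append("".join(parts))
    return rows


def column_conservation(msa: Sequence[str]) -> np.ndarray:
    """Per-column conservation: modal-base frequency over non-gap count
    (0 for all-gap columns)."""
    ncol = len(msa[0])
    out = np.zeros(ncol)
    for j in range(ncol):
        col = [row[j] for row in msa if row[j] != "-"]
        if col:
            out[j] = Counter(col).most_common(1)[0][1] / len(col)
    return out


def select_probe_window(
    msa: Sequence[str], length: int = 22, name: str = "probe"
) -> ProbeCandidate:
    """Most conserved fixed-length window of an alignment as a probe.

    Ties go to the leftmost window.  The probe sequence is the modal
    (non-gap) base per column; all-gap columns are dropped, so the emitted
    oligo can be shorter than the window.
    """
    if not msa:
        raise ValueError("empty alignment")
    ncol = len(msa[0])
    if ncol < length:
        raise ValueError(f"alignment has {ncol} columns, window needs {length}")
    cons = column_conservation(msa)
    window_means = np.convolve(cons, np.ones(length) / length, mode="valid")
    start = int(np.argmax(window_means))  # argmax is leftmost on ties
    seq_chars = []
    for j in range(start, start + length):
        col = [row[j] for row in msa if row[j] != "-"]
        if not col:
            continue
        counts = Counter(col)
        top = max(counts.values())
        seq_chars.append(sorted(c for c, v in counts.items() if v == top)[0])
    sequence = "".join(seq_chars)
    return ProbeCandidate(
        name=name,
        sequence=sequence,
        msa_start=start,
        conservation=float(window_means[start]),
        at_percent=at_content(sequence),
    )


def probe_record(
    candidate: ProbeCandidate, fluor_codes: Sequence[str] = ()
) -> dict:
    """Synthesis-table row: (name, 5'-F-<sequence>, comma-joined channels)."""
    bad = set(fluor_codes) - set(FLUOR_CODES)
    if bad:
        raise ValueError(f"unknown fluorophore codes: {sorted(bad)}")
    ordered = [c for c in FLUOR_CODES if c in set(fluor_codes)]
    return {
        "name": candidate.name,
        "sequence": "5'-F-" + candidate.sequence,
        "fluorophores": ", ".join(ordered),
    }


def design_probe(
    consensi: Sequence[str],
    family: str,
    length: int = 22,
    fluor_codes: Sequence[str] = (),
) -> ProbeCandidate:
    """Convenience: align a family's consensi and select its probe window."""
    msa = align_consensi(consensi)
    cand = select_probe_window(msa, length=length, name=f"{family}_oligo")
    return ProbeCandidate(
        cand.name, cand.sequence, cand.msa_start, cand.conservation,
        cand.at_percent, tuple(fluor_codes),
    )
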