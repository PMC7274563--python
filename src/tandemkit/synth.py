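"""Seeded synthetic long reads with known tandem-repeat structure.

The generator emulates early single-molecule CLR-style reads: >= 5 kb, with
a composite error rate around 10% split into substitutions, insertions and
deletions (defaults 4%/3%/3%).  Tandem arrays use random monomers with an
AT fraction drawn from the range observed for real plant satellite families
(0.42-0.79); monomers are rejection-sampled until their cyclic 12-mer
spectrum is duplicate-free, which gives the array a clean phase structure
for k-mer counting and period estimation.  Truth intervals are recorded on
the error-free read and mapped through the indel process, never re-detected.

Every operation is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detect import ReadPattern
from .seqio import LongRead, write_fasta

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SynthSpec:
    """Recipe for one synthetic read."""

    seed: int
    unit_length: int = 120
    at_fraction: float = 0.60
    copies: int = 10
    pattern: ReadPattern = ReadPattern.FULL
    flank_bp: int = 1000
    sub_rate: float = 0.04
    ins_rate: float = 0.03
    del_rate: float = 0.03
    read_len_target: int = 8000
    unit_length2: Optional[int] = None  # second family for COMBO reads
    read_id: Optional[str] = None
    # explicit monomers (shared across reads of one simulated family);
    # when omitted, fresh monomers are drawn from the spec's seed
    monomer: Optional[str] = None
    monomer2: Optional[str] = None

    def __post_init__(self) -> None:
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(r < 0 or r > 1 for r in rates) or sum(rates) >= 1:
            raise ValueError("error rates must lie in [0,1] and sum below 1")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")


@dataclass
class TruthRecord:
    """Ground-truth annotation for one synthetic read."""

    read_id: str
    regions: List[Tuple[int, int, int, str]]  # (start, end, unit_length, label)
    pattern: ReadPattern


def _draw(rng: np.random.Generator, length: int, at_fraction: float = 0.5) -> str:
    p_at = at_fraction / 2.0
    p_cg = (1.0 - at_fraction) / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_cg, p_cg, p_at])
    return BASES[idx].tobytes().decode()


def _cyclic_kmers_unique(monomer: str, k: int = 12) -> bool:
    if len(monomer) < k:
        return True
    doubled = monomer + monomer
    return len({doubled[i : i + k] for i in range(len(monomer))}) == len(monomer)


def random_monomer(length: int, at_fraction: float, seed: int) -> str:
    """Random monomer with the given expected AT fraction.

    Rejection-resampled until the cyclic 12-mer spectrum of the monomer is
    duplicate-free, so a perfect array of it has exactly ``length`` distinct
    12-mers, one per phase.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        m = _draw(rng, length, at_fraction)
        if _cyclic_kmers_unique(m):
            return m
    raise RuntimeError("could not draw a cyclic-duplicate-free monomer")


def mutate(
    seq: str,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    seed: int,
    return_map: bool = False,
):
    """Apply per-base independent substitution/insertion/deletion noise.

    Substitution replaces the base with a uniformly chosen different base;
    insertion adds a uniform base after the position; deletion removes it.
    Expected output length is ``len(seq) * (1 + ins_rate - del_rate)``.
    With ``return_map``, also returns an array mapping every original
    coordinate (and the end coordinate) to its position in the output.
    """
    rng = np.random.default_rng(seed)
    n = len(seq)
    ev = rng.random(n)
    ins = rng.random(n) < ins_rate
    sub_choice = rng.integers(1, 4, size=n)  # offset to a different base
    ins_base = rng.integers(0, 4, size=n)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    base_idx = np.zeros(n, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        base_idx[arr == b] = i
    out = bytearray()
    coord_map = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        coord_map[i] = len(out)
        if ev[i] < del_rate:
            pass
        elif ev[i] < del_rate + sub_rate:
            out.append(BASES[(base_idx[i] + sub_choice[i]) % 4])
        else:
            out.append(arr[i])
        if ins[i]:
            out.append(BASES[ins_base[i]])
    coord_map[n] = len(out)
    mutated = out.decode()
    if return_map:
        return mutated, coord_map
    return mutated


def _child_seed(seed: int, i: int) -> int:
    return int((seed * 1_000_003 + i) % (2**31 - 1))


def build_read(spec: SynthSpec) -> Tuple[LongRead, TruthRecord]:
    """Assemble one synthetic read with its ground truth.

    Pattern layouts (fractions of the error-free read):
      FULL          one array spanning >= 95%
      PARTIAL       one array covering 20-60%
      INTERSPERSED  two arrays of the same monomer, separated by > 1 kb
      COMBO         two arrays of different monomers (requires unit_length2)
      NO_TR_LOW_COMPLEXITY  a microsatellite run or pure random sequence
    """
    rng = np.random.default_rng(spec.seed)
    monomer = spec.monomer or random_monomer(
        spec.unit_length, spec.at_fraction, _child_seed(spec.seed, 1)
    )
    if spec.monomer is not None:
        spec = replace(spec, unit_length=len(spec.monomer))
    label = f"TR{spec.unit_length}"
    pieces: List[str] = []
    truth: List[Tuple[int, int, int, str]] = []

    def add_flank(n: int) -> None:
        if n > 0:
            pieces.append(_draw(rng, n))

    def add_array(mono: str, ncopies: int, lab: str) -> None:
        start = sum(len(p) for p in pieces)
        arr = mono * ncopies
        pieces.append(arr)
        truth.append((start, start + len(arr), len(mono), lab))

    L = spec.read_len_target
    if spec.pattern is ReadPattern.FULL:
        ncopies = max(spec.copies, int(np.ceil(0.96 * L / spec.unit_length)))
        pad = max(0, (L - ncopies * spec.unit_length) // 2)
        pad = min(pad, int(0.02 * L))
        add_flank(pad)
        add_array(monomer, ncopies, label)
        add_flank(pad)
    elif spec.pattern is ReadPattern.PARTIAL:
        frac = rng.uniform(0.20, 0.60)
        ncopies = max(2, int(round(frac * L / spec.unit_length)))
        ncopies = max(ncopies, min(spec.copies, int(0.60 * L / spec.unit_length)))
        rest = max(0, L - ncopies * spec.unit_length)
        left = int(rest * rng.uniform(0.25, 0.75))
        add_flank(left)
        add_array(monomer, ncopies, label)
        add_flank(rest - left)
    elif spec.pattern is ReadPattern.INTERSPERSED:
        ncopies = max(2, spec.copies)
        gap = int(rng.uniform(1200, 2500))
        rest = max(0, L - 2 * ncopies * spec.unit_length - gap)
        add_flank(rest // 2)
        add_array(monomer, ncopies, label)
        add_flank(gap)
        add_array(monomer, ncopies, label)
        add_flank(rest - rest // 2)
    elif spec.pattern is ReadPattern.COMBO:
        if spec.monomer2 is not None:
            spec = replace(spec, unit_length2=len(spec.monomer2))
        if not spec.unit_length2 or (
            abs(spec.unit_length2 - spec.unit_length)
            <= 0.10 * min(spec.unit_length2, spec.unit_length)
        ):
            raise ValueError(
                "COMBO requires unit_length2 differing from unit_length by > 10%"
            )
        monomer2 = spec.monomer2 or random_monomer(
            spec.unit_length2, spec.at_fraction, _child_seed(spec.seed, 2)
        )
        n1 = max(2, spec.copies)
        n2 = max(2, int(round(spec.copies * spec.unit_length / spec.unit_length2)))
        gap = int(rng.uniform(1200, 2500))
        rest = max(0, L - n1 * spec.unit_length - n2 * spec.unit_length2 - gap)
        add_flank(rest // 2)
        add_array(monomer, n1, label)
        add_flank(gap)
        add_array(monomer2, n2, f"TR{spec.unit_length2}")
        add_flank(rest - rest // 2)
    elif spec.pattern is ReadPattern.NO_TR_LOW_COMPLEXITY:
        if rng.random() < 0.5:
            unit = ["A", "AT", "CA", "AAT", "AG"][int(rng.integers(0, 5))]
            run = unit * (int(rng.uniform(500, 1500)) // len(unit))
            rest = max(0, L - len(run))
            add_flank(rest // 2)
            pieces.append(run)
            add_flank(rest - rest // 2)
        else:
            add_flank(L)
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown pattern {spec.pattern}")

    clean = "".join(pieces)
    mutated, coord_map = mutate(
        clean, spec.sub_rate, spec.ins_rate, spec.del_rate,
        _child_seed(spec.seed, 3), return_map=True,
    )
    read_id = spec.read_id or f"s{spec.seed}"
    read = LongRead(read_id, f"synthetic_{read_id}", mutated)
    mapped = [
        (int(coord_map[s]), int(coord_map[e]), u, lab) for s, e, u, lab in truth
    ]
    return read, TruthRecord(read_id, mapped, spec.pattern)


def build_library(
    specs: Sequence[SynthSpec],
    n_background: int = 0,
    seed: int = 0,
    fasta_path: Optional[str | Path] = None,
    truth_path: Optional[str | Path] = None,
) -> Tuple[List[LongRead], pd.DataFrame]:
    """Build a read library from specs plus random >= 5 kb background reads.

    Returns the reads and a truth table; optionally writes FASTA and TSV.
    Background reads carry empty truth and pattern NO_TR_LOW_COMPLEXITY.
    """
    reads: List[LongRead] = []
    rows: List[dict] = []
    for spec in specs:
        read, rec = build_read(spec)
        reads.append(read)
        if rec.regions:
            for s, e, u, lab in rec.regions:
                rows.append(
                    dict(read_id=rec.read_id, start=s, end=e, unit_length=u,
                         family=lab, pattern=rec.pattern.value)
                )
        else:
            rows.append(
                dict(read_id=rec.read_id, start=-1, end=-1, unit_length=0,
                     family="", pattern=rec.pattern.value)
            )
    rng = np.random.default_rng(_child_seed(seed, 999))
    for i in range(n_background):
        length = int(rng.integers(5000, 12000))
        read_id = f"bg{i}"
        reads.append(LongRead(read_id, f"background_{read_id}", _draw(rng, length)))
        rows.append(
            dict(read_id=read_id, start=-1, end=-1, unit_length=0, family="",
                 pattern=ReadPattern.NO_TR_LOW_COMPLEXITY.value)
        )
    truth = pd.DataFrame(
        rows, columns=["read_id", "start", "end", "unit_length", "family", "pattern"]
    )
    if fasta_path is not None:
        write_fasta(reads, fasta_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return reads, truth
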