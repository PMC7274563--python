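"""The polySeq family catalog: build, assign, name, count.

Each tandem-repeat family is represented by a fixed-size block — its
consensus tiled to exactly 1 kb (2 kb for units over 500 bp, so every block
holds at least two copies and shows diagonals in a dot plot).  Blocks are
concatenated, in discovery order, into a single reference sequence
("polySeq") whose kilobase offsets identify families at a glance: a read
seed-matched against the polySeq lights up the block(s) of the family or
families it carries.  New families are only ever appended, so block offsets
are stable for the life of a catalog.

Family names follow the ``<prefix><unit length, zero-padded to 3>`` rule,
e.g. unit 120 -> ``HuluTR120``, optionally suffixed with the discovery read
(``HuluTR120-r479``).  Abundance is expressed as TR-containing reads per
million library reads before any filtering.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .consensus import ConsensusUnit
from .detect import TRRegion
from .selfalign import seed_matches
from .seqio import LongRead

NEW_FAMILY = "NEW"


@dataclass
class TRFamily:
    name: str
    unit_length_bp: int
    consensus: str
    block_start: int
    block_end: int
    discovery_read: str = ""
    known_alias: Optional[str] = None

    @property
    def block_offset_kb(self) -> int:
        return self.block_start // 1000


@dataclass
class PolySeq:
    """Ordered family blocks and their concatenated reference sequence."""

    families: List[TRFamily] = field(default_factory=list)
    sequence: str = ""

    def block_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (f.name, f.unit_length_bp, f.block_start, f.block_end,
                 f.known_alias or "")
                for f in self.families
            ],
            columns=["name", "unit_length_bp", "block_start", "block_end", "alias"],
        )

    def write(self, fasta_path: str | Path, table_path: str | Path) -> None:
        """Single-record FASTA plus a sidecar TSV block table."""
        fasta_path = Path(fasta_path)
        with open(fasta_path, "w") as fh:
            fh.write(f">polySeq{len(self.families)}\n")
            for i in range(0, len(self.sequence), 80):
                fh.write(self.sequence[i : i + 80] + "\n")
        self.block_table().to_csv(table_path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        data = [
            dict(name=f.name, unit_length_bp=f.unit_length_bp, consensus=f.consensus,
                 block_start=f.block_start, block_end=f.block_end,
                 discovery_read=f.discovery_read, known_alias=f.known_alias)
            for f in self.families
        ]
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PolySeq":
        data = json.loads(Path(path).read_text())
        return build_polyseq(
            [
                dict(name=d["name"], consensus=d["consensus"],
                     unit_length_bp=d.get("unit_length_bp"),
                     discovery_read=d.get("discovery_read", ""),
                     known_alias=d.get("known_alias"))
                for d in data
            ]
        )


@dataclass
class FamilyAssignment:
    read_id: str
    region: Optional[TRRegion]
    family_name: str  # a catalog family name, or NEW_FAMILY
    block_offset_kb: int  # -1 for NEW
    match_fraction: float


def make_block(consensus: str, large_unit_threshold: int = 500) -> str:
    """Tile a consensus end-to-end into a 1-kb block (2 kb for large units)."""
    if not consensus:
        raise ValueError("consensus must be nonempty")
    block_len = 2000 if len(consensus) > large_unit_threshold else 1000
    reps = -(-block_len // len(consensus))
    return (consensus * reps)[:block_len]


def build_polyseq(families: Sequence[dict]) -> PolySeq:
    """Concatenate family blocks in the given order.

    Each entry needs ``name`` and ``consensus``; ``unit_length_bp``,
    ``discovery_read`` and ``known_alias`` are optional.  Duplicate names
    raise.
    """
    names = [f["name"] for f in families]
    if len(set(names)) != len(names):
        raise ValueError("duplicate family names")
    ps = PolySeq()
    for entry in families:
        block = make_block(entry["consensus"])
        fam = TRFamily(
            name=entry["name"],
            unit_length_bp=entry.get("unit_length_bp") or len(entry["consensus"]),
            consensus=entry["consensus"],
            block_start=len(ps.sequence),
            block_end=len(ps.sequence) + len(block),
            discovery_read=entry.get("discovery_read", ""),
            known_alias=entry.get("known_alias"),
        )
        ps.families.append(fam)
        ps.sequence += block
    return ps


def _union_length(intervals: List[Tuple[int, int]]) -> int:
    covered = 0
    cur_end = 0
    for s, e in sorted(intervals):
        s = max(s, cur_end)
        if e > s:
            covered += e - s
            cur_end = e
    return covered


def _matched_per_block(
    ps: PolySeq, read_seq: str, word: int
) -> Tuple[Dict[str, int], Dict[str, int], int]:
    """Per block: total matched bases, and the union of read positions the
    block's matches cover.  The union discriminates a real family hit (the
    block tiles the read's array) from a single chance word amplified by
    tandem copy-number on both sides."""
    ms = seed_matches(read_seq, ps.sequence, word=word, both_strands=True,
                      query_id="read", target_id="polySeq")
    per_block: Dict[str, int] = {f.name: 0 for f in ps.families}
    q_intervals: Dict[str, List[Tuple[int, int]]] = {f.name: [] for f in ps.families}
    total = 0
    for m in ms.matches:
        t0, t1 = m.t_start, m.t_start + m.length
        total += m.length
        for f in ps.families:
            ov = min(t1, f.block_end) - max(t0, f.block_start)
            if ov > 0:
                per_block[f.name] += ov
                q_intervals[f.name].append((m.q_start, m.q_start + m.length))
    read_cov = {name: _union_length(iv) for name, iv in q_intervals.items()}
    return per_block, read_cov, total


def assign_read(
    read: LongRead,
    regions: Sequence[TRRegion],
    ps: PolySeq,
    word: int = 10,
    min_match_frac: float = 0.10,
    min_region_cov: float = 0.20,
) -> List[FamilyAssignment]:
    """Assign a read's repeat content to catalog families by block matching.

    The read is seed-matched (both strands) against the polySeq; each
    block's match fraction is its matched bases over all matched bases.
    One assignment is emitted per block with fraction >= ``min_match_frac``
    whose matches also cover >= ``min_region_cov`` of the read region they
    correspond to (a real family hit tiles the array; an amplified chance
    word covers almost nothing), sorted by fraction descending.  A read
    with a qualifying (non-low-complexity) region but no qualifying block
    is assigned ``NEW``.  Reads without any qualifying region get no
    assignment at all, so junk reads can neither join nor found families.
    """
    qualifying = [r for r in regions if not r.low_complexity]
    if not qualifying or not ps.families:
        return []
    per_block, read_cov, total = _matched_per_block(ps, read.sequence, word)
    out: List[FamilyAssignment] = []
    if total > 0:
        fams = {f.name: f for f in ps.families}
        scored = sorted(
            ((n, b / total) for n, b in per_block.items() if b / total >= min_match_frac),
            key=lambda kv: -kv[1],
        )
        for name, frac in scored:
            fam = fams[name]
            region = min(
                qualifying,
                key=lambda r: abs(r.period_bp - fam.unit_length_bp) / fam.unit_length_bp,
            )
            if read_cov[name] < min_region_cov * (region.end - region.start):
                continue
            out.append(
                FamilyAssignment(read.read_id, region, name, fam.block_offset_kb, frac)
            )
    if not out:
        region = max(qualifying, key=lambda r: r.support_bp)
        out.append(FamilyAssignment(read.read_id, region, NEW_FAMILY, -1, 0.0))
    return out


def family_name(
    unit_length_bp: int,
    prefix: str = "HuluTR",
    read_id: Optional[str] = None,
    taken: Optional[Iterable[str]] = None,
) -> str:
    """Build a family name: prefix + unit length zero-padded to 3 digits.

    ``(120, read_id="r479") -> "HuluTR120-r479"``.  When ``taken`` names are
    supplied, collisions between distinct families of equal rounded unit
    length get letter suffixes (``HuluTR120b``).
    """
    if unit_length_bp <= 0:
        raise ValueError("unit length must be positive")
    base = f"{prefix}{unit_length_bp:03d}"
    if taken:
        taken = set(taken)
        suffix = ""
        letters = iter("bcdefghijklmnopqrstuvwxyz")
        while base + suffix in taken:
            suffix = next(letters)
        base = base + suffix
    if read_id:
        return f"{base}-{read_id}"
    return base


def consensus_identity(consensus: str, family: TRFamily) -> float:
    """Rotation- and strand-aware identity of a consensus to a family's unit.

    The consensus is located inside the family's tiled unit (free-end edit
    alignment, so the arbitrary monomer phase does not matter) on both
    strands; identity = 1 - edit distance / consensus length.
    """
    import edlib

    from ._dna import revcomp

    reps = 2 + len(consensus) // max(1, len(family.consensus))
    target = family.consensus * reps
    best = min(
        edlib.align(consensus, target, mode="HW")["editDistance"],
        edlib.align(revcomp(consensus), target, mode="HW")["editDistance"],
    )
    return max(0.0, 1.0 - best / len(consensus))


def register_new_family(
    ps: PolySeq,
    read: LongRead,
    region: TRRegion,
    consensus_unit: ConsensusUnit,
    prefix: str = "HuluTR",
    min_identity: float = 0.90,
) -> Tuple[PolySeq, TRFamily]:
    """Append a newly discovered family to the catalog (idempotently).

    If the consensus already matches an existing family's block at seed
    identity >= ``min_identity`` the existing family is returned and the
    catalog is unchanged.
    """
    for fam in ps.families:
        if consensus_identity(consensus_unit.consensus, fam) >= min_identity:
            return ps, fam
    name = family_name(
        consensus_unit.rounded_size, prefix=prefix,
        taken=[f.name for f in ps.families],
    )
    block = make_block(consensus_unit.consensus)
    fam = TRFamily(
        name=name,
        unit_length_bp=consensus_unit.rounded_size,
        consensus=consensus_unit.consensus,
        block_start=len(ps.sequence),
        block_end=len(ps.sequence) + len(block),
        discovery_read=read.read_id,
    )
    ps.families.append(fam)
    ps.sequence += block
    return ps, fam


def abundance_table(
    assignments: Iterable[FamilyAssignment], library_size: int
) -> pd.DataFrame:
    """Per-family read counts and reads-per-million of the original library.

    ``library_size`` is the read count before any filtering.  Rows are
    sorted by abundance, then by unit length (descending), following the
    summary-table convention.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    per_family: Dict[str, set] = {}
    for a in assignments:
        if a.family_name == NEW_FAMILY:
            continue
        per_family.setdefault(a.family_name, set()).add(a.read_id)
    rows = []
    for name, readset in per_family.items():
        n = len(readset)
        rpm = int(math.floor(n * 1e6 / library_size + 0.5))
        rows.append((name, n, rpm))
    df = pd.DataFrame(rows, columns=["family", "n_reads", "reads_per_million"])
    unit = df["family"].str.extract(r"(\d+)", expand=False).astype(float)
    df = (
        df.assign(_unit=unit)
        .sort_values(["n_reads", "_unit"], ascending=[False, False])
        .drop(columns="_unit")
        .reset_index(drop=True)
    )
    return df


def known_families(prefix: str = "HuluTR") -> List[dict]:
    """Seed entries for the previously published hop repeat families.

    The telomeric unit is the canonical plant repeat; the subtelomeric and
    rDNA families are represented by synthetic placeholder consensi of the
    published unit lengths (their true consensi are not shipped), which is
    enough to reserve their blocks and names in a new catalog.
    """
    from .synth import random_monomer

    entries = [
        dict(name="Telo", consensus="CCCTAAA", unit_length_bp=7,
             known_alias="telomere"),
        dict(name=f"{prefix}180", consensus=random_monomer(180, 0.62, 180_001),
             unit_length_bp=180, known_alias="HSR0"),
        dict(name=f"{prefix}385", consensus=random_monomer(385, 0.61, 385_001),
             unit_length_bp=385, known_alias="HSR1"),
        dict(name=f"{prefix}335", consensus=random_monomer(335, 0.55, 335_001),
             unit_length_bp=335, known_alias="5SrDNA"),
    ]
    return entries
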