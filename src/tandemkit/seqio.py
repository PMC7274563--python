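"""FASTA input/output and the read-length admission rule.

Long single-molecule reads arrive as plain FASTA.  Headers produced by the
k-mer screening convention look like ``>hulupacbiokf_r0055``; the trailing
``_r<digits>`` token is normalized to a short read identifier (``r55``,
leading zeros stripped) so the same molecule is one identity however it is
written.  Any other header keeps its first whitespace-delimited token as the
identifier.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_READ_NUM = re.compile(r"^.*_r(\d+)$")


def normalize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase *seq* and replace characters outside {A,C,G,T,N} with N.

    Returns the cleaned sequence and the number of replaced characters.
    """
    seq = seq.upper()
    bad = sum(1 for c in seq if c not in _VALID)
    if bad:
        seq = "".join(c if c in _VALID else "N" for c in seq)
    return seq, bad


def parse_read_id(title: str) -> str:
    """Derive the canonical short read id from a FASTA title.

    ``x_r0055`` -> ``r55``; anything else -> first whitespace token.
    """
    token = title.split()[0] if title.split() else title
    m = _READ_NUM.match(token)
    if m:
        return "r" + str(int(m.group(1)))
    return token


@dataclass
class LongRead:
    """One input long read: stable identifier, original title, ACGTN sequence."""

    read_id: str
    title: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be nonempty")
        if set(self.sequence) - _VALID:
            raise ValueError(
                f"read {self.read_id}: sequence contains characters outside ACGTN"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> List[LongRead]:
    """Read a multi-record FASTA into LongReads, preserving input order.

    Lowercase bases are uppercased; characters outside {A,C,G,T,N} are
    replaced by N (count logged as a warning).  A record with an empty
    sequence raises a ValueError naming the offending header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    reads: List[LongRead] = []
    n_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq, bad = normalize_sequence(str(rec.seq))
        n_replaced += bad
        if not seq:
            raise ValueError(f"empty sequence for record '{rec.description}'")
        reads.append(LongRead(parse_read_id(rec.description), rec.description, seq))
    if n_replaced:
        logger.warning(
            "%s: replaced %d non-ACGTN characters with N", path.name, n_replaced
        )
    return reads


def filter_by_length(
    reads: Iterable[LongRead], min_len: int = 5000
) -> List[LongRead]:
    """Retain reads with length >= *min_len* (inclusive), preserving order.

    The admission rule for single-molecule reads "greater than 5 kb" is
    applied inclusively at the boundary; the threshold is configurable.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in reads if r.length >= min_len]


def write_fasta(
    reads: Sequence[LongRead], path: str | Path, line_width: int = 80
) -> Path:
    """Write reads as FASTA with fixed line wrap; round-trips with read_fasta."""
    path = Path(path)
    records = [
        SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in reads
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)
    return path
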