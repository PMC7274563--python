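"""Small shared DNA helpers."""

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_at_counts(seq: str) -> tuple[int, int]:
    """(A+T count, A+C+G+T count) of a sequence; N and other symbols excluded."""
    at = seq.count("A") + seq.count("T")
    acgt = at + seq.count("C") + seq.count("G")
    return at, acgt
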