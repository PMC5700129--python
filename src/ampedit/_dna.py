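"""Small DNA string helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str, allow_n: bool = False) -> bool:
    alphabet = set("ACGTN" if allow_n else "ACGT")
    return bool(seq) and set(seq) <= alphabet


def hamming(a: str, b: str) -> int:
    """Substitution distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
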