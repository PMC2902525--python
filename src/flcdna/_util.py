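"""Small shared helpers: alphabet conversion, rounding, IUPAC semantics.

The package stores every sequence as DNA (A/C/G/T/N); RNA letters appear
only at presentation time (PAS hexamers, Kozak consensus) via :func:`to_rna`.
"""

from __future__ import annotations

import math

DNA_BASES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC degenerate nucleotide codes (DNA alphabet).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def to_rna(seq: str) -> str:
    """Present a DNA string in the RNA alphabet (T -> U)."""
    return seq.replace("T", "U").replace("t", "u")


def to_dna(seq: str) -> str:
    """Canonicalize an input string to uppercase DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves rounding up (97.5 -> 98)."""
    return int(math.floor(x + 0.5))


def iupac_match(base: str, code: str) -> bool:
    """Does a concrete base satisfy an IUPAC degenerate code?

    An N in the subject sequence matches nothing except code N: degenerate
    positions assert base identity, which an unknown base cannot provide.
    """
    allowed = IUPAC.get(code)
    if allowed is None:
        raise ValueError(f"invalid IUPAC code {code!r}")
    if base == "N":
        return code == "N"
    return base in allowed


def validate_iupac(pattern: str) -> None:
    bad = [c for c in pattern if c not in IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC character(s) {bad!r} in pattern {pattern!r}")
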