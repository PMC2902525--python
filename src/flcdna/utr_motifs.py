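"""Simplified UTR regulatory-motif scanning.

A small descriptor engine matching degenerate (IUPAC) core segments,
optional variable-length spacers between segments, and flanking stem arms
that must be reverse-complementary within a mismatch budget — enough to
express hairpin motifs such as the iron-responsive element (IRE) or a
SECIS-like stem-loop without thermodynamic folding.

The shipped descriptors are deliberately simplified, synthetic stand-ins
for the curated patterns of the UTR-motif databases: they capture each
motif's published core and stem geometry approximately and are meant to
exercise the engine, not to reproduce curated-database search results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from ._util import COMPLEMENT, iupac_match, to_dna, validate_iupac

__all__ = [
    "MotifDescriptor",
    "MotifHit",
    "scan_motif",
    "BUILTIN_DESCRIPTORS",
    "load_descriptors",
]


@dataclass(frozen=True)
class MotifDescriptor:
    """One degenerate-pattern + stem motif.

    Structure matched, 5'->3':

        flank5  stem5(stem_len)  core[0]  spacer[0]  core[1] ... core[-1]  stem3

    where stem3 must be reverse-complementary to stem5 with at most
    ``max_stem_mismatch`` mismatched pairs, and spacer lengths range over
    ``spacer_ranges`` (min, max) nt. ``stem_len`` 0 with a single core
    reduces to plain degenerate string matching.
    """

    name: str
    cores: tuple[str, ...]
    spacer_ranges: tuple[tuple[int, int], ...] = ()
    stem_len: int = 0
    max_stem_mismatch: int = 0
    flank5: str = ""
    target_utr: str = "utr3"  # "utr5" | "utr3"

    def __post_init__(self) -> None:
        if self.stem_len < 0:
            raise ValueError(f"{self.name}: negative stem_len")
        if len(self.spacer_ranges) != max(0, len(self.cores) - 1):
            raise ValueError(
                f"{self.name}: {len(self.cores)} cores need "
                f"{len(self.cores) - 1} spacer ranges"
            )
        for pattern in (*self.cores, self.flank5):
            validate_iupac(to_dna(pattern))
        # canonicalize any RNA letters in the descriptor to DNA
        object.__setattr__(self, "cores", tuple(to_dna(c) for c in self.cores))
        object.__setattr__(self, "flank5", to_dna(self.flank5))


@dataclass(frozen=True)
class MotifHit:
    transcript_id: str
    motif: str
    start: int  # 1-based, UTR-local, includes flank and stem arms
    end: int  # 1-based inclusive
    stem_mismatches: int


def _match_at(seq: str, pattern: str, pos: int) -> bool:
    if pos < 0 or pos + len(pattern) > len(seq):
        return False
    return all(iupac_match(seq[pos + i], c) for i, c in enumerate(pattern))


def _stem_mismatches(seq: str, left: int, right: int, stem_len: int) -> Optional[int]:
    """Mismatch count pairing seq[left:left+stem_len] with
    seq[right:right+stem_len] as a reverse-complementary stem."""
    if left < 0 or right + stem_len > len(seq):
        return None
    mm = 0
    for k in range(stem_len):
        five = seq[left + k]
        three = seq[right + stem_len - 1 - k]
        if "N" in (five, three) or three != five.translate(COMPLEMENT):
            mm += 1
    return mm


def _core_layouts(
    seq: str, desc: MotifDescriptor, start: int
) -> list[int]:
    """End positions (exclusive) of full core+spacer assemblies starting at
    ``start``; depth-first over spacer lengths."""
    ends: list[int] = []

    def walk(pos: int, core_idx: int) -> None:
        core = desc.cores[core_idx]
        if not _match_at(seq, core, pos):
            return
        nxt = pos + len(core)
        if core_idx == len(desc.cores) - 1:
            ends.append(nxt)
            return
        lo, hi = desc.spacer_ranges[core_idx]
        for gap in range(lo, hi + 1):
            walk(nxt + gap, core_idx + 1)

    walk(start, 0)
    return ends


def scan_motif(
    utr_seq: str,
    descriptor: MotifDescriptor,
    transcript_id: str = "",
) -> list[MotifHit]:
    """All matches of a descriptor in one UTR (given 5'->3'), ascending by
    start position; duplicate (start, end) spans are reported once."""
    seq = to_dna(utr_seq)
    hits: dict[tuple[int, int], MotifHit] = {}
    n_flank = len(descriptor.flank5)
    for i in range(len(seq)):
        for end in _core_layouts(seq, descriptor, i):
            if descriptor.stem_len:
                left = i - descriptor.stem_len
                mm = _stem_mismatches(seq, left, end, descriptor.stem_len)
                if mm is None or mm > descriptor.max_stem_mismatch:
                    continue
            else:
                left, mm = i, 0
            if n_flank and not _match_at(seq, descriptor.flank5, left - n_flank):
                continue
            start0 = left - n_flank
            end0 = end + descriptor.stem_len  # exclusive
            key = (start0 + 1, end0)
            if key not in hits or mm < hits[key].stem_mismatches:
                hits[key] = MotifHit(transcript_id, descriptor.name, start0 + 1, end0, mm)
    return sorted(hits.values(), key=lambda h: (h.start, h.end))


# Simplified synthetic stand-in descriptors (see module docstring).
BUILTIN_DESCRIPTORS: dict[str, MotifDescriptor] = {
    "IRE": MotifDescriptor(
        name="IRE",
        cores=("CAGTGH",),  # apical loop, 3' base degenerate
        stem_len=5,
        max_stem_mismatch=1,
        flank5="C",  # unpaired 5' bulged C
        target_utr="utr5",
    ),
    "SECIS": MotifDescriptor(
        name="SECIS",
        cores=("ATGA", "AAR", "GA"),
        spacer_ranges=((15, 40), (10, 30)),
        stem_len=7,
        max_stem_mismatch=2,
        target_utr="utr3",
    ),
    "ADH_DRE": MotifDescriptor(
        name="ADH_DRE",
        cores=("GCYGCYGCYGAY",),  # plain degenerate consensus, no stem
        target_utr="utr3",
    ),
}


def load_descriptors(path: str) -> dict[str, MotifDescriptor]:
    """Read descriptors from a YAML file: a list of mappings with keys
    name, cores, spacer_ranges, stem_len, max_stem_mismatch, flank5,
    target_utr."""
    with open(path) as fh:
        blocks = yaml.safe_load(fh)
    out: dict[str, MotifDescriptor] = {}
    for block in blocks:
        desc = MotifDescriptor(
            name=block["name"],
            cores=tuple(block["cores"]),
            spacer_ranges=tuple(tuple(r) for r in block.get("spacer_ranges", ())),
            stem_len=int(block.get("stem_len", 0)),
            max_stem_mismatch=int(block.get("max_stem_mismatch", 0)),
            flank5=block.get("flank5", ""),
            target_utr=block.get("target_utr", "utr3"),
        )
        out[desc.name] = desc
    return out
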