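"""Poly(A)-tail detection, polyadenylation-signal (PAS) calling and hexamer
discovery.

The mature 3' end of a polyadenylated transcript carries a hexameric signal
(canonically AAUAAA, second most common AUUAAA) within ~35 nt upstream of
the cleavage/poly(A) site. This module

* detects and trims the 3'-terminal poly(A) tail,
* screens the <=35-nt window immediately upstream of the tail for the two
  canonical signals (AAUAAA taking precedence), and
* for transcripts carrying neither, counts every hexamer present in those
  windows exhaustively — equivalent to exact fixed-length pattern discovery
  (L = W = 6) — reporting hexamers supported by a minimum number of
  transcripts.

Hexamers are stored as DNA internally and reported in the RNA alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from ._util import to_rna
from .seq_io import TranscriptRecord

__all__ = [
    "PolyACall",
    "PasClass",
    "PasCall",
    "HexamerTable",
    "detect_polya",
    "pas_window",
    "scan_pas",
    "discover_hexamers",
]

CANONICAL_PAS = "AATAAA"
SECONDARY_PAS = "ATTAAA"


@dataclass(frozen=True)
class PolyACall:
    """Location of a 3'-terminal poly(A) tail (1-based), if any."""

    transcript_id: str
    tail_start: Optional[int]  # 1-based position of first tail base
    tail_len: int
    trimmed_len: int

    @property
    def has_tail(self) -> bool:
        return self.tail_start is not None


class PasClass(str, Enum):
    AAUAAA = "AAUAAA"
    AUUAAA = "AUUAAA"
    OTHER = "other"
    NONE = "none"


@dataclass
class PasCall:
    """PAS verdict for one tailed transcript.

    ``offset`` is the number of nucleotides strictly between the 3' end of
    the hexamer and the first tail base (0 = immediately adjacent).
    """

    transcript_id: str
    pas_class: PasClass
    hexamer: Optional[str] = None  # RNA alphabet
    offset: Optional[int] = None


@dataclass
class HexamerTable:
    """Per-transcript presence counts of hexamers in PAS windows.

    A transcript contributes at most 1 to any hexamer's count however many
    times the hexamer occurs in its window.
    """

    counts: dict[str, int]  # RNA hexamer -> number of transcripts
    n_transcripts_scanned: int
    min_support: int = 30

    def rows(self) -> list[tuple[str, int]]:
        """Hexamers with count >= min_support, by count desc then lexicographic."""
        kept = [(h, c) for h, c in self.counts.items() if c >= self.min_support]
        return sorted(kept, key=lambda hc: (-hc[1], hc[0]))


def detect_polya(
    record: TranscriptRecord,
    min_tail: int = 10,
    max_mismatch_frac: float = 0.1,
) -> PolyACall:
    """Find the longest 3'-terminal segment that looks like a poly(A) tail.

    A qualifying segment has length >= ``min_tail``, A-fraction >=
    1 - ``max_mismatch_frac``, and begins and ends with A (mismatched bases
    are interior, so the tail boundary never sits on a non-A base). The
    longest such suffix wins; its first base is ``tail_start``.
    """
    seq = record.seq
    n = len(seq)
    if n == 0 or seq[-1] != "A" or n < min_tail:
        return PolyACall(record.id, None, 0, n)
    best = None
    a_count = 0  # number of A's in the current suffix
    need = 1.0 - max_mismatch_frac
    for length in range(1, n + 1):
        if seq[n - length] == "A":
            a_count += 1
        if (
            length >= min_tail
            and seq[n - length] == "A"
            and a_count >= need * length
        ):
            best = length
    if best is None:
        return PolyACall(record.id, None, 0, n)
    return PolyACall(record.id, n - best + 1, best, n - best)


def pas_window(record: TranscriptRecord, polya: PolyACall, window: int = 35) -> str:
    """The <=``window``-nt stretch ending immediately before the tail (DNA)."""
    if not polya.has_tail:
        raise ValueError(f"record {record.id!r}: no poly(A) tail, no PAS window")
    end = polya.tail_start - 1  # 0-based exclusive
    return record.seq[max(0, end - window) : end]


def scan_pas(
    record: TranscriptRecord,
    polya: PolyACall,
    window: int = 35,
) -> PasCall:
    """Screen the upstream window for the canonical signals.

    AAUAAA anywhere in the window takes precedence over AUUAAA; the 3'-most
    occurrence is the one reported. Transcripts with neither are classed
    ``other`` (window long enough to hold a hexamer) or ``none``.
    """
    win = pas_window(record, polya, window)
    for dna, cls in ((CANONICAL_PAS, PasClass.AAUAAA), (SECONDARY_PAS, PasClass.AUUAAA)):
        pos = win.rfind(dna)
        if pos != -1:
            # bases strictly between hexamer end and tail start
            offset = len(win) - (pos + 6)
            return PasCall(record.id, cls, to_rna(dna), offset)
    if len(win) >= 6:
        return PasCall(record.id, PasClass.OTHER)
    return PasCall(record.id, PasClass.NONE)


def discover_hexamers(
    windows: Iterable[str],
    min_support: int = 30,
) -> HexamerTable:
    """Exhaustively count hexamer presence across PAS windows.

    ``windows`` are the same upstream windows used by :func:`scan_pas`, for
    the transcripts lacking both canonical signals. Exact fixed-length
    discovery (pattern length = window length = 6, no wildcards) degenerates
    to sliding a 6-nt frame over each window and recording presence.
    """
    counts: dict[str, int] = {}
    n = 0
    for win in windows:
        n += 1
        seen: set[str] = set()
        for i in range(len(win) - 5):
            seen.add(win[i : i + 6])
        for hexamer in seen:
            key = to_rna(hexamer)
            counts[key] = counts.get(key, 0) + 1
    return HexamerTable(counts=counts, n_transcripts_scanned=n, min_support=min_support)


def assign_discovered(calls: Sequence[PasCall], windows: Sequence[str], table: HexamerTable) -> None:
    """Resolve ``other`` calls in place: attach the best-supported discovered
    hexamer present in each transcript's window (3'-most occurrence)."""
    ranked = {h: rank for rank, (h, _) in enumerate(table.rows())}
    for call, win in zip(calls, windows):
        if call.pas_class is not PasClass.OTHER:
            continue
        present = {
            to_rna(win[i : i + 6]): i  # later i overwrites: 3'-most occurrence
            for i in range(len(win) - 5)
            if to_rna(win[i : i + 6]) in ranked
        }
        if present:
            best = min(present, key=lambda h: ranked[h])
            call.hexamer = best
            call.offset = len(win) - (present[best] + 6)
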