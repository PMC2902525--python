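"""Two-species ortholog comparison.

Transcripts from the two species sharing the same best translated-search
subject (gene identity) are paired — the lowest-E-value transcript
representing each species — and their ORF and 3'UTR regions compared by
global (Needleman-Wunsch) alignment. Percent identity is matches over
alignment columns, excluding columns that lie in a terminal gap of either
sequence, rounded half-up to the nearest whole number.

Scoring defaults: match +1, mismatch -1, gap -2 (linear), terminal gaps
free. These are package defaults, configurable per call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import Align

from ._util import round_half_up
from .fullength import FullLengthCall

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologPair",
    "pair_by_identity",
    "global_identity",
    "compare_pair_regions",
    "similarity_histogram",
]


@dataclass
class OrthologPair:
    """One shared gene identity with its per-region percent identities."""

    gene_id: str
    id_a: str
    id_b: str
    orf_identity: Optional[int] = None
    utr3_identity: Optional[int] = None


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    # terminal gaps free
    aligner.end_gap_score = 0.0
    return aligner


def global_identity(
    seq_x: str,
    seq_y: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> int:
    """Global-alignment percent identity, terminal-gap columns excluded,
    rounded half-up to an integer."""
    if not seq_x or not seq_y:
        raise ValueError("empty sequence in identity computation")
    aligner = _make_aligner(match, mismatch, gap)
    alignment = aligner.align(seq_x, seq_y)[0]
    row_x, row_y = alignment[0], alignment[1]
    n_cols = len(row_x)

    def gap_run(row: str, reverse: bool) -> int:
        it = reversed(row) if reverse else row
        n = 0
        for c in it:
            if c != "-":
                break
            n += 1
        return n

    lead = max(gap_run(row_x, False), gap_run(row_y, False))
    trail = max(gap_run(row_x, True), gap_run(row_y, True))
    hi = n_cols - trail
    if hi <= lead:
        raise ValueError("alignment has no non-terminal columns")
    matches = sum(
        1 for k in range(lead, hi) if row_x[k] == row_y[k] and row_x[k] != "-"
    )
    return round_half_up(100.0 * matches / (hi - lead))


def pair_by_identity(
    calls_a: Sequence[FullLengthCall],
    calls_b: Sequence[FullLengthCall],
) -> list[OrthologPair]:
    """One pair per subject identity present in both species.

    When a species has several transcripts for one subject, the lowest
    E-value transcript represents it (logged).
    """

    def best_by_subject(calls: Sequence[FullLengthCall]) -> dict[str, FullLengthCall]:
        best: dict[str, FullLengthCall] = {}
        for call in calls:
            sid = call.best_hit_subject
            if sid is None:
                continue
            prev = best.get(sid)
            if prev is None:
                best[sid] = call
            else:
                logger.info(
                    "subject %s: multiple transcripts in one species; keeping lowest E-value",
                    sid,
                )
                if (call.best_hit_evalue, call.transcript_id) < (
                    prev.best_hit_evalue, prev.transcript_id
                ):
                    best[sid] = call
        return best

    best_a = best_by_subject(calls_a)
    best_b = best_by_subject(calls_b)
    shared = sorted(set(best_a) & set(best_b))
    return [
        OrthologPair(gene_id=sid, id_a=best_a[sid].transcript_id, id_b=best_b[sid].transcript_id)
        for sid in shared
    ]


def compare_pair_regions(
    pair: OrthologPair,
    seq_a: str,
    seq_b: str,
    orf_a: tuple[int, int],
    orf_b: tuple[int, int],
    trimmed_len_a: int,
    trimmed_len_b: int,
) -> OrthologPair:
    """Fill per-region identities for one pair. ORF spans are 1-based
    inclusive; the 3'UTR runs from the stop codon to the tail start. A pair
    with an empty region on either side is left uncomputed (warned)."""
    sa, ea = orf_a
    sb, eb = orf_b
    pair.orf_identity = global_identity(seq_a[sa - 1 : ea], seq_b[sb - 1 : eb])
    utr3_a = seq_a[ea:trimmed_len_a]
    utr3_b = seq_b[eb:trimmed_len_b]
    if not utr3_a or not utr3_b:
        logger.warning("pair %s: empty 3'UTR, identity skipped", pair.gene_id)
    else:
        pair.utr3_identity = global_identity(utr3_a, utr3_b)
    return pair


def similarity_histogram(
    pairs: Sequence[OrthologPair],
    region: str = "orf",
) -> tuple[dict[int, int], float]:
    """Counts per integer percent bin (80..100) and the fraction of pairs
    at 98-99% identity."""
    attr = {"orf": "orf_identity", "utr3": "utr3_identity"}[region]
    values = [getattr(p, attr) for p in pairs if getattr(p, attr) is not None]
    counts = {b: 0 for b in range(80, 101)}
    for v in values:
        counts[min(max(v, 80), 100)] = counts.get(min(max(v, 80), 100), 0) + 1
    frac_98_99 = (
        sum(1 for v in values if v in (98, 99)) / len(values) if values else 0.0
    )
    return counts, frac_98_99
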