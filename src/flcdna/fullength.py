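"""Full-length cDNA classification.

A full-length cDNA is a clone-derived sequence with a conserved start codon,
a complete ORF, a stop codon and a poly(A) tail. The conserved-start rule
accepts a transcript whose best translated-search hit (E < 1e-5 by default)
has an in-frame ATG further upstream of the alignment start, at the same
position (when the alignment begins at the reference's first residue), or
mapping within the first 10 amino acids of the reference protein.

Transcripts that satisfy every criterion but have an implausibly short
3'UTR with no PAS hexamer in the upstream window are flagged as likely
internal-poly(A) artifacts (oligo-dT priming inside the transcript body).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from ._util import STOP_CODONS
from .polyadenylation import PasClass, PolyACall, scan_pas
from .seq_io import AlignmentHit, TranscriptRecord
from .transcript_features import OrfAnnotation, annotate_orf

__all__ = [
    "Status",
    "FullLengthCall",
    "select_best_hit",
    "has_conserved_start",
    "classify_full_length",
]


class Status(str, Enum):
    FULL_LENGTH = "full_length"
    INTERNAL_POLYA_SUSPECT = "internal_polyA_suspect"
    MISSING_CONSERVED_START = "missing_conserved_start"
    MISSING_STOP = "missing_stop"
    MISSING_POLYA = "missing_polyA"
    NO_SIGNIFICANT_HIT = "no_significant_hit"


@dataclass
class FullLengthCall:
    transcript_id: str
    status: Status
    conserved_start_pos: Optional[int] = None
    best_hit_subject: Optional[str] = None
    best_hit_evalue: Optional[float] = None
    orf: Optional[OrfAnnotation] = None
    reasons: list[str] = field(default_factory=list)


def select_best_hit(
    hits: Sequence[AlignmentHit], e_cut: float = 1e-5
) -> Optional[AlignmentHit]:
    """Best significant hit for one query: minimum E-value below ``e_cut``,
    ties broken by higher percent identity, then lexicographic subject id."""
    if not hits:
        return None
    query_ids = {h.query_id for h in hits}
    if len(query_ids) > 1:
        raise ValueError(f"hits span multiple query ids: {sorted(query_ids)}")
    passing = [h for h in hits if h.evalue < e_cut]
    if not passing:
        return None
    return min(passing, key=lambda h: (h.evalue, -h.pct_identity, h.subject_id))


def has_conserved_start(
    record: TranscriptRecord,
    hit: AlignmentHit,
    max_subject_aa: int = 10,
) -> tuple[bool, Optional[int]]:
    """Locate the 5'-most qualifying in-frame ATG for this hit.

    Qualifying positions, all in the hit's reading frame:

    a. upstream of the alignment start, provided no in-frame stop codon
       intervenes between the candidate ATG and the alignment start (a stop
       there would preclude the ATG initiating the aligned protein);
    b. the alignment start itself when the alignment begins at the
       reference's first residue;
    c. aligned codons mapping to reference residues <= ``max_subject_aa``
       (inclusive).

    Returns (found, 1-based position of the 5'-most qualifying ATG).
    """
    seq = record.seq
    q0 = hit.q_start - 1  # 0-based alignment start
    candidates: list[int] = []

    # (a) walk upstream codon by codon until an in-frame stop
    pos = q0 - 3
    while pos >= 0:
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            break
        if codon == "ATG":
            candidates.append(pos)
        pos -= 3
    # (b) + (c): aligned codons mapping to subject residues <= max_subject_aa
    for aa in range(hit.s_start, min(hit.s_end, max_subject_aa) + 1):
        p = q0 + 3 * (aa - hit.s_start)
        if seq[p : p + 3] == "ATG":
            candidates.append(p)

    if not candidates:
        return (False, None)
    return (True, min(candidates) + 1)


def classify_full_length(
    record: TranscriptRecord,
    hits: Sequence[AlignmentHit],
    polya: PolyACall,
    orf: Optional[OrfAnnotation] = None,
    min_utr3: int = 10,
    e_cut: float = 1e-5,
    max_subject_aa: int = 10,
    pas_window_len: int = 35,
) -> FullLengthCall:
    """Apply the four-part definition; every input yields exactly one call.

    Failure gates mirror the definition's order: significant hit ->
    conserved start -> complete ORF with stop -> poly(A) tail. A transcript
    passing all four but whose 3'UTR is shorter than ``min_utr3`` with no
    canonical PAS in the upstream window is judged an internal-poly(A)
    suspect.
    """
    reasons: list[str] = []
    best = select_best_hit(hits, e_cut)
    if best is None:
        reasons.append(f"no hit with E < {e_cut:g}")
        return FullLengthCall(record.id, Status.NO_SIGNIFICANT_HIT, reasons=reasons)

    found, start_pos = has_conserved_start(record, best, max_subject_aa)
    if not found:
        reasons.append(
            f"no in-frame ATG at/upstream of alignment start or within first "
            f"{max_subject_aa} aa of {best.subject_id}"
        )
        return FullLengthCall(
            record.id,
            Status.MISSING_CONSERVED_START,
            best_hit_subject=best.subject_id,
            best_hit_evalue=best.evalue,
            reasons=reasons,
        )

    if orf is None:
        orf = annotate_orf(record, start_pos, trimmed_len=polya.trimmed_len or None)
    if orf is None:
        reasons.append("no in-frame stop codon before sequence end")
        return FullLengthCall(
            record.id,
            Status.MISSING_STOP,
            conserved_start_pos=start_pos,
            best_hit_subject=best.subject_id,
            best_hit_evalue=best.evalue,
            reasons=reasons,
        )

    if not polya.has_tail:
        reasons.append("no poly(A) tail detected")
        return FullLengthCall(
            record.id,
            Status.MISSING_POLYA,
            conserved_start_pos=start_pos,
            best_hit_subject=best.subject_id,
            best_hit_evalue=best.evalue,
            orf=orf,
            reasons=reasons,
        )

    utr3_len = polya.trimmed_len - orf.orf_end
    if utr3_len < min_utr3:
        pas = scan_pas(record, polya, window=pas_window_len)
        if pas.pas_class not in (PasClass.AAUAAA, PasClass.AUUAAA):
            reasons.append(
                f"3'UTR of {utr3_len} nt (< {min_utr3}) with no PAS hexamer: "
                "likely internal poly(A)"
            )
            return FullLengthCall(
                record.id,
                Status.INTERNAL_POLYA_SUSPECT,
                conserved_start_pos=start_pos,
                best_hit_subject=best.subject_id,
                best_hit_evalue=best.evalue,
                orf=orf,
                reasons=reasons,
            )

    reasons.append("conserved start + complete ORF + stop + poly(A) tail")
    return FullLengthCall(
        record.id,
        Status.FULL_LENGTH,
        conserved_start_pos=start_pos,
        best_hit_subject=best.subject_id,
        best_hit_evalue=best.evalue,
        orf=orf,
        reasons=reasons,
    )
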