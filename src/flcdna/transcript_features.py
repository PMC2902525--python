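"""ORF/UTR annotation and length summaries.

Given an accepted (conserved) start codon, the ORF runs from that ATG
through the first in-frame stop codon, stop included. UTR lengths are
measured on the poly(A)-trimmed sequence: the 3'UTR ends where the tail
begins, so homopolymer tail length never inflates UTR statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._util import STOP_CODONS
from .seq_io import TranscriptRecord

__all__ = ["OrfAnnotation", "LengthSummary", "annotate_orf", "summarize"]


@dataclass(frozen=True)
class OrfAnnotation:
    """ORF and UTR coordinates for one transcript.

    Coordinates are 1-based inclusive; ``orf_end`` is the last base of the
    stop codon, so ``orf_len`` includes the stop codon and is a multiple
    of 3.
    """

    transcript_id: str
    orf_start: int
    orf_end: int
    utr5_len: int
    utr3_len: int
    trimmed_len: int

    @property
    def orf_len(self) -> int:
        return self.orf_end - self.orf_start + 1


@dataclass
class LengthSummary:
    """Cohort length statistics in the style of a summary table plus
    fixed-width histograms of ORF and 3'UTR lengths."""

    n: int
    mean_seq_len: float
    mean_orf_len: float
    mean_utr5_len: float
    mean_utr3_len: float
    min_orf_len: int
    max_orf_len: int
    min_utr3_len: int
    max_utr3_len: int
    orf_hist: dict[int, int]  # bin left edge -> count
    utr3_hist: dict[int, int]
    bin_width_orf: int
    bin_width_utr: int


def annotate_orf(
    record: TranscriptRecord,
    conserved_start_pos: int,
    trimmed_len: Optional[int] = None,
) -> Optional[OrfAnnotation]:
    """Extend from the accepted ATG to the first in-frame stop codon.

    ``trimmed_len`` is the poly(A)-trimmed sequence length (defaults to the
    full length when no tail was found). Returns None when no in-frame stop
    occurs before the trimmed end — a "missing stop" state the classifier
    propagates rather than an exception.
    """
    if trimmed_len is None:
        trimmed_len = len(record.seq)
    seq = record.seq[:trimmed_len]
    s0 = conserved_start_pos - 1
    if seq[s0 : s0 + 3] != "ATG":
        raise ValueError(
            f"record {record.id!r}: no ATG at claimed start position {conserved_start_pos}"
        )
    for i in range(s0, trimmed_len - 2, 3):
        if seq[i : i + 3] in STOP_CODONS and i > s0:
            orf_end = i + 3  # 1-based inclusive end of stop codon
            return OrfAnnotation(
                transcript_id=record.id,
                orf_start=conserved_start_pos,
                orf_end=orf_end,
                utr5_len=conserved_start_pos - 1,
                utr3_len=trimmed_len - orf_end,
                trimmed_len=trimmed_len,
            )
    return None


def summarize(
    annotations: Sequence[OrfAnnotation],
    bin_width_orf: int = 300,
    bin_width_utr: int = 100,
) -> LengthSummary:
    """Arithmetic means and left-closed histograms [k*w, (k+1)*w)."""
    if not annotations:
        raise ValueError("no annotations to summarize")
    orf_lens = np.array([a.orf_len for a in annotations])
    utr3_lens = np.array([a.utr3_len for a in annotations])
    utr5_lens = np.array([a.utr5_len for a in annotations])
    seq_lens = np.array([a.trimmed_len for a in annotations])

    def hist(values: np.ndarray, width: int) -> dict[int, int]:
        bins = (values // width) * width
        edges, counts = np.unique(bins, return_counts=True)
        return {int(e): int(c) for e, c in zip(edges, counts)}

    return LengthSummary(
        n=len(annotations),
        mean_seq_len=float(seq_lens.mean()),
        mean_orf_len=float(orf_lens.mean()),
        mean_utr5_len=float(utr5_lens.mean()),
        mean_utr3_len=float(utr3_lens.mean()),
        min_orf_len=int(orf_lens.min()),
        max_orf_len=int(orf_lens.max()),
        min_utr3_len=int(utr3_lens.min()),
        max_utr3_len=int(utr3_lens.max()),
        orf_hist=hist(orf_lens, bin_width_orf),
        utr3_hist=hist(utr3_lens, bin_width_utr),
        bin_width_orf=bin_width_orf,
        bin_width_utr=bin_width_utr,
    )
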