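"""Kozak start-codon context profiling.

The translation-initiation context spanning positions -4..+4 around the
initiator ATG (8 bases: four upstream, the ATG, and the first base of the
second codon) is extracted from every annotated transcript with at least
four bases of 5'UTR. The profile holds per-position base counts and
frequencies, a modal consensus string, and per-position information content
R_i = 2 - H_i bits (H_i the Shannon entropy of position i's base
frequencies) — the quantity a sequence-logo letter stack displays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from ._util import DNA_BASES, to_rna
from .seq_io import TranscriptRecord
from .transcript_features import OrfAnnotation

__all__ = ["KozakProfile", "extract_context", "extract_contexts", "build_profile"]

POSITIONS = (-4, -3, -2, -1, 1, 2, 3, 4)
_BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}


@dataclass
class KozakProfile:
    """Position x base (A,C,G,T) counts for the 8-nt start context."""

    counts: np.ndarray  # shape (8, 4), integer
    n_contexts: int
    tied_positions: tuple[int, ...] = ()

    @property
    def freqs(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)

    @property
    def info_bits(self) -> np.ndarray:
        """Per-position information content, 2 - H_i, in [0, 2] bits."""
        f = self.freqs
        with np.errstate(invalid="ignore", divide="ignore"):
            h = -np.where(f > 0, f * np.log2(f), 0.0).sum(axis=1)
        return 2.0 - h

    @property
    def consensus(self) -> str:
        """Modal base per position (DNA); ties resolved in A>C>G>T order and
        recorded in ``tied_positions``."""
        letters = []
        ties = []
        for i in range(8):
            row = self.counts[i]
            best = int(row.argmax())  # argmax returns first max: A>C>G>T order
            if (row == row[best]).sum() > 1:
                ties.append(POSITIONS[i])
            letters.append(DNA_BASES[best])
        self.tied_positions = tuple(ties)
        return "".join(letters)

    @property
    def consensus_rna(self) -> str:
        return to_rna(self.consensus)

    def merge(self, other: "KozakProfile") -> "KozakProfile":
        """Count additivity: profiling A+B equals merging profiles of A, B."""
        return KozakProfile(
            counts=self.counts + other.counts,
            n_contexts=self.n_contexts + other.n_contexts,
        )


def extract_context(record: TranscriptRecord, orf: OrfAnnotation) -> Optional[str]:
    """The 8-mer spanning -4..+4 around the initiator ATG, or None.

    Excluded (None): transcripts with fewer than 4 nt of 5'UTR, and contexts
    containing an N (an unknown base contributes no count).
    """
    s0 = orf.orf_start - 1
    if s0 < 4 or s0 + 4 > len(record.seq):
        return None
    ctx = record.seq[s0 - 4 : s0 + 4]
    if "N" in ctx:
        return None
    return ctx


def extract_contexts(
    pairs: Iterable[tuple[TranscriptRecord, OrfAnnotation]],
) -> tuple[list[str], int]:
    """Extract all contexts; returns (contexts, excluded_count) so that
    n_contexts + excluded_count equals the number of annotated transcripts."""
    contexts: list[str] = []
    excluded = 0
    for record, orf in pairs:
        ctx = extract_context(record, orf)
        if ctx is None:
            excluded += 1
        else:
            contexts.append(ctx)
    return contexts, excluded


def build_profile(contexts: Sequence[str]) -> KozakProfile:
    """Count bases per position over 8-mer contexts.

    Positions +1..+3 must be the start codon ATG in every context — anything
    else signals an extraction bug upstream.
    """
    if not contexts:
        raise ValueError("no contexts to profile")
    counts = np.zeros((8, 4), dtype=np.int64)
    for ctx in contexts:
        if len(ctx) != 8:
            raise ValueError(f"context {ctx!r} is not 8 nt")
        if ctx[4:7] != "ATG":
            raise ValueError(f"context {ctx!r}: positions +1..+3 are not ATG")
        for i, base in enumerate(ctx):
            counts[i, _BASE_INDEX[base]] += 1
    return KozakProfile(counts=counts, n_contexts=len(contexts))


def plot_logo(profile: KozakProfile, path: str) -> None:
    """Write a minimal information-content letter plot (optional; needs
    matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    f = profile.freqs
    info = profile.info_bits
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fig, ax = plt.subplots(figsize=(6, 3))
    for i in range(8):
        bottom = 0.0
        order = np.argsort(f[i])  # small letters first, tallest on top
        for j in order:
            height = f[i, j] * info[i]
            if height <= 0:
                continue
            base = to_rna(DNA_BASES[j])
            ax.text(
                i, bottom + height / 2, base,
                ha="center", va="center",
                fontsize=8 + 16 * height, color=colors[DNA_BASES[j]],
                family="monospace", weight="bold",
            )
            bottom += height
    ax.set_xticks(range(8), [str(p) for p in POSITIONS])
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xlabel("position relative to start codon")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
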