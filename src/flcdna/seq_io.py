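"""Input/output for the formats the pipeline touches.

Reads FASTA/FASTQ transcript sets and translated-search (BLAST outfmt-6
style) tabular hits, applies Phred-style quality trimming, and writes FASTA.

Conventions confined to this module:

* files and reports use 1-based inclusive coordinates; internal computation
  is 0-based half-open;
* the internal alphabet is DNA — U is converted to T on input and the record
  flagged ``rna_input``;
* minus-strand HSPs (qstart > qend) are skipped with a warning: the pipeline
  assumes directional, 5'->3' oriented cDNA clones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from ._util import to_dna

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptRecord",
    "AlignmentHit",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "quality_trim",
    "read_blast_tab",
    "write_blast_tab",
]


@dataclass
class TranscriptRecord:
    """One cDNA consensus sequence with species label and optional qualities.

    ``species`` distinguishes the two closely related species being compared
    (e.g. channel vs blue catfish); any short label is accepted, "A"/"B" by
    convention.
    """

    id: str
    seq: str
    species: str = "A"
    quals: Optional[Sequence[int]] = None
    rna_input: bool = False
    trim_span: Optional[tuple[int, int]] = None  # 1-based inclusive, post-trim

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.seq = to_dna(self.seq)
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: {len(self.quals)} quality scores for "
                f"{len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentHit:
    """One translated-search HSP against a protein reference.

    Query coordinates are 1-based nucleotide positions on the plus strand
    (``q_start < q_end``); subject coordinates are 1-based amino-acid
    positions. ``frame`` follows the convention frame = ((q_start-1) mod 3)+1,
    i.e. the codon phase of the alignment start on the query.
    """

    query_id: str
    subject_id: str
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    frame: int
    pct_identity: float = 100.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative E-value")
        if not (1 <= self.q_start < self.q_end):
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: bad query span "
                f"{self.q_start}..{self.q_end}"
            )
        if not (1 <= self.s_start <= self.s_end):
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: bad subject span "
                f"{self.s_start}..{self.s_end}"
            )
        q_span = self.q_end - self.q_start + 1
        s_span = self.s_end - self.s_start + 1
        if q_span != 3 * s_span:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: query span {q_span} nt "
                f"is not 3x subject span {s_span} aa"
            )
        if self.frame != (self.q_start - 1) % 3 + 1:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: frame {self.frame} "
                f"inconsistent with q_start {self.q_start}"
            )


def _species_from_description(description: str, token: str, default: str) -> str:
    # header token style: ">id species=B other stuff"
    for word in description.split():
        if word.startswith(token + "="):
            return word.split("=", 1)[1]
    return default


def read_fasta(
    path: str | Path,
    species_token: str = "species",
    default_species: str = "A",
) -> list[TranscriptRecord]:
    """Read a FASTA file into :class:`TranscriptRecord` objects.

    The species label is parsed from a ``species=X`` token in the header
    description when present, else ``default_species``. Sequences are
    uppercased; U is converted to T with ``rna_input`` set.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        raw = str(entry.seq)
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(
            TranscriptRecord(
                id=entry.id,
                seq=raw,
                species=_species_from_description(
                    entry.description, species_token, default_species
                ),
                rna_input="U" in raw.upper(),
            )
        )
    if not records:
        raise ValueError(f"no FASTA entries in {path}")
    return records


def read_fastq(
    path: str | Path,
    species_token: str = "species",
    default_species: str = "A",
) -> list[TranscriptRecord]:
    """Read Sanger FASTQ (Phred+33) with per-base qualities."""
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fastq"):
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        raw = str(entry.seq)
        records.append(
            TranscriptRecord(
                id=entry.id,
                seq=raw,
                species=_species_from_description(
                    entry.description, species_token, default_species
                ),
                quals=list(entry.letter_annotations["phred_quality"]),
                rna_input="U" in raw.upper(),
            )
        )
    if not records:
        raise ValueError(f"no FASTQ entries in {path}")
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} species={rec.species}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def quality_trim(record: TranscriptRecord, q_cut: int = 20) -> Optional[TranscriptRecord]:
    """Keep the longest contiguous run of bases with quality >= ``q_cut``.

    Returns a new record whose ``trim_span`` holds the retained 1-based
    inclusive coordinates on the input, or None when no base survives (the
    caller drops such records). Raises if the record carries no qualities.
    """
    if record.quals is None:
        raise ValueError(f"record {record.id!r} has no quality scores")
    best_start, best_len = 0, 0
    run_start = None
    for i, q in enumerate(list(record.quals) + [-1]):  # sentinel flushes last run
        if q >= q_cut:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    if best_len == 0:
        logger.warning("record %s: every base below Q%d, dropped", record.id, q_cut)
        return None
    return TranscriptRecord(
        id=record.id,
        seq=record.seq[best_start : best_start + best_len],
        species=record.species,
        quals=list(record.quals[best_start : best_start + best_len]),
        rna_input=record.rna_input,
        trim_span=(best_start + 1, best_start + best_len),
    )


def read_blast_tab(path: str | Path) -> list[AlignmentHit]:
    """Parse 12-column tabular hits (qid, sid, pident, length, mismatch,
    gapopen, qstart, qend, sstart, send, evalue, bitscore).

    Minus-strand HSPs (qstart > qend) are skipped with a warning; malformed
    lines raise with their line number.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated fields, got {len(fields)}"
                )
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
            if qstart > qend:
                logger.warning(
                    "%s:%d: minus-strand HSP %s->%s skipped (qstart %d > qend %d)",
                    path, lineno, qid, sid, qstart, qend,
                )
                continue
            try:
                hits.append(
                    AlignmentHit(
                        query_id=qid,
                        subject_id=sid,
                        evalue=evalue,
                        q_start=qstart,
                        q_end=qend,
                        s_start=sstart,
                        s_end=send,
                        frame=(qstart - 1) % 3 + 1,
                        pct_identity=pident,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_blast_tab(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits back in the 12-column dialect (alignment length in aa*3;
    mismatch/gapopen/bitscore filled with placeholder zeros)."""
    with open(path, "w") as fh:
        for h in hits:
            length = h.q_end - h.q_start + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{h.pct_identity:.1f}", length,
                        0, 0, h.q_start, h.q_end, h.s_start, h.s_end,
                        f"{h.evalue:.2e}", 0,
                    )
                )
                + "\n"
            )
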