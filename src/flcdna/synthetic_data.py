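"""Two-species synthetic transcript sets with full ground truth.

Every downstream stage is testable without external data: the generator
emits transcripts assembled as

    5'UTR + ORF (ATG ... in-frame stop, no internal stop) + 3'UTR + poly(A)

with a Kozak context drawn from a position-frequency model (modal string
AAACATGG in DNA), a PAS hexamer planted 8-24 nt upstream of the tail at
configurable class frequencies (defaults 0.55 AAUAAA / 0.26 AUUAAA, the
remainder drawn from the common variant hexamers), translated-search hit
records standing in for BLASTX output, cross-species ortholog copies at
configurable per-region divergence, and paralog/allele triples.

Construction guarantees that make the truth table exact for the pipeline:

* ORF interiors are built codon-wise from sense codons, so the first
  in-frame stop after the ATG is the true stop;
* 5'UTRs are scrubbed of in-frame ATGs, so the conserved-start search
  returns the true start;
* the region that can fall inside the PAS scan window is scrubbed of
  unintended canonical hexamers, so the scanned class equals the planted
  class;
* the planted hexamer is separated from the tail by a gap of non-A bases
  long enough that tail detection cannot absorb it.

Defect decoys (missing tail, missing stop, internal poly(A), missing
conserved start, no significant hit) are planted among species-specific
transcripts at configurable rates; shared-identity genes are kept
defect-free so the ortholog-pair truth stays clean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._util import STOP_CODONS, to_rna
from .seq_io import AlignmentHit, TranscriptRecord, write_blast_tab, write_fasta

__all__ = ["SynthConfig", "TruthTable", "Triple", "SimResult", "simulate", "mutate"]

SENSE_CODONS = np.array(
    ["".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS]
)
BASES = np.array(list("ACGT"))
NON_A = np.array(list("CGT"))
CANONICAL = "AATAAA"
SECONDARY = "ATTAAA"

# common non-canonical variant hexamers (DNA) with table weights
VARIANT_HEXAMERS = {
    "TATAAA": 48, "AAAAAA": 43, "ATAAAA": 40, "TGTTTT": 38, "TAAAAA": 38,
    "AAAAAC": 34, "TTTTTG": 33, "TTTAAA": 33, "AGTAAA": 32, "AATATA": 30,
}

DEFAULT_KOZAK_PWM = {
    -4: {"A": 0.40, "C": 0.25, "G": 0.20, "T": 0.15},
    -3: {"A": 0.45, "C": 0.10, "G": 0.30, "T": 0.15},  # purine bias at -3
    -2: {"A": 0.40, "C": 0.25, "G": 0.15, "T": 0.20},
    -1: {"A": 0.30, "C": 0.40, "G": 0.15, "T": 0.15},
    4: {"A": 0.25, "C": 0.15, "G": 0.45, "T": 0.15},
}


@dataclass
class SynthConfig:
    """Study conditions for the generator. Lengths in nt."""

    seed: int
    n_transcripts: int = 1000  # per species
    n_shared_identities: int = 416
    # lognormal length models (mean values match the cohort the package
    # characterizes: ORF ~689 bp clipped to [114, 1416], 3'UTR ~243 bp)
    orf_len_mu: float = 6.434
    orf_len_sigma: float = 0.45
    orf_len_clip: tuple[int, int] = (114, 1416)
    utr3_len_mu: float = 5.31
    utr3_len_sigma: float = 0.60
    utr3_len_clip: tuple[int, int] = (45, 2000)
    utr5_len_mu: float = 3.30
    utr5_len_sigma: float = 0.55
    utr5_len_clip: tuple[int, int] = (4, 200)
    frac_short_utr5: float = 0.05  # 5'UTR of 0-3 nt: Kozak context unavailable
    tail_len_range: tuple[int, int] = (12, 45)
    kozak_pwm: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_KOZAK_PWM.items()})
    pas_freqs: dict = field(default_factory=lambda: {CANONICAL: 0.55, SECONDARY: 0.26})
    pas_gap_range: tuple[int, int] = (8, 24)  # non-A gap between hexamer and tail
    ortholog_divergence_orf: float = 0.015
    ortholog_divergence_utr: float = 0.05
    defect_rates: dict = field(
        default_factory=lambda: {
            "missing_polya": 0.0,
            "missing_stop": 0.0,
            "internal_polya": 0.0,
            "no_hit": 0.0,
            "missing_start": 0.0,
        }
    )
    # paralog/allele triples
    n_allele_triples: int = 100
    n_paralog_triples: int = 100
    triple_len: int = 600
    allele_divergence: float = 0.002
    paralog_divergence: float = 0.08
    species_divergence: float = 0.02

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.pas_freqs.values())
        if not 0 < total <= 1.0 + 1e-9:
            raise ValueError("pas_freqs must sum to at most 1 (remainder = other)")
        if self.n_shared_identities > self.n_transcripts:
            raise ValueError("n_shared_identities exceeds n_transcripts")


@dataclass
class TruthTable:
    transcripts: pd.DataFrame  # one row per emitted transcript
    pairs: pd.DataFrame  # one row per shared gene identity
    triples: pd.DataFrame  # one row per paralog/allele triple


@dataclass
class Triple:
    triple_id: str
    relation: str  # "paralog" | "allele"
    ids: tuple[str, str, str]
    seqs: tuple[str, str, str]


@dataclass
class SimResult:
    records: dict[str, list[TranscriptRecord]]
    hits: list[AlignmentHit]
    truth: TruthTable
    triples: list[Triple]
    config: SynthConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for species, recs in self.records.items():
            write_fasta(recs, outdir / f"species_{species}.fasta")
        write_blast_tab(self.hits, outdir / "hits.tsv")
        self.truth.transcripts.to_csv(outdir / "truth_transcripts.tsv", sep="\t", index=False)
        self.truth.pairs.to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
        self.truth.triples.to_csv(outdir / "truth_triples.tsv", sep="\t", index=False)
        with open(outdir / "triples.fasta", "w") as fh:
            for t in self.triples:
                for tid, seq in zip(t.ids, t.seqs):
                    fh.write(f">{tid}\n{seq}\n")


def mutate(
    seq: str,
    sub_rate: float,
    indel_rate: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Per-base independent substitution to a uniformly chosen different
    base; optional length-1 indels (default off, preserving reading frame)."""
    if not 0 <= sub_rate < 1 or not 0 <= indel_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < sub_rate
    if hit.any():
        idx = np.flatnonzero(hit)
        for i in idx:
            others = [b for b in "ACGT" if b != arr[i]]
            arr[i] = others[rng.integers(0, 3)]
    out = list(arr)
    if indel_rate > 0:
        result = []
        for c in out:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            result.append(c)
            if indel_rate / 2 <= r < indel_rate:
                result.append(BASES[rng.integers(0, 4)])  # insertion
        out = result
    return "".join(out)


# ---------------------------------------------------------------------------
# internal construction helpers


def _rand_bases(rng: np.random.Generator, n: int, alphabet: np.ndarray = BASES) -> str:
    if n <= 0:
        return ""
    return "".join(alphabet[rng.integers(0, len(alphabet), n)])


def _draw_len(rng, mu, sigma, clip, multiple_of: int = 1) -> int:
    lo, hi = clip
    val = int(round(float(rng.lognormal(mu, sigma))))
    val = min(max(val, lo), hi)
    if multiple_of > 1:
        val = (val // multiple_of) * multiple_of
        val = min(max(val, (lo + multiple_of - 1) // multiple_of * multiple_of), hi)
    return val


def _draw_pwm_base(rng, dist: dict[str, float]) -> str:
    bases = sorted(dist)
    probs = np.array([dist[b] for b in bases], dtype=float)
    probs = probs / probs.sum()
    return bases[rng.choice(len(bases), p=probs)]


def _scrub_inframe_atg(utr5: list[str], rng: np.random.Generator) -> None:
    """Remove in-frame ATGs from a 5'UTR (frame anchored at the start codon
    immediately after the UTR). Mutates the list in place."""
    n = len(utr5)
    changed = True
    while changed:
        changed = False
        for p in range(n % 3, n - 2, 3):
            if utr5[p] == "A" and utr5[p + 1] == "T" and utr5[p + 2] == "G":
                utr5[p + 1] = "C"
                changed = True


def _scrub_canonicals(
    seq: list[str],
    lo: int,
    hi: int,
    protected: range,
    rng: np.random.Generator,
    codon_frame_anchor: Optional[int] = None,
) -> None:
    """Destroy unintended canonical PAS hexamers whose span intersects
    [lo, hi), leaving ``protected`` untouched. When ``codon_frame_anchor``
    is given (0-based ORF start), replacements keep affected in-frame codons
    sense (never create a stop)."""
    changed = True
    while changed:
        changed = False
        text = "".join(seq)
        for motif in (CANONICAL, SECONDARY):
            start = max(0, lo - 5)
            while True:
                p = text.find(motif, start, hi + 5)
                if p == -1:
                    break
                span = range(p, p + 6)
                if span == protected or (
                    p == protected.start and p + 6 == protected.stop
                ):
                    start = p + 1
                    continue
                candidates = [q for q in span if q not in protected]
                fixed = False
                for q in candidates:
                    for repl in "CGT":
                        if repl == seq[q]:
                            continue
                        old = seq[q]
                        seq[q] = repl
                        if codon_frame_anchor is not None:
                            c0 = codon_frame_anchor + 3 * ((q - codon_frame_anchor) // 3)
                            if 0 <= c0 and c0 + 3 <= len(seq):
                                codon = "".join(seq[c0 : c0 + 3])
                                if codon in STOP_CODONS:
                                    seq[q] = old
                                    continue
                        fixed = True
                        break
                    if fixed:
                        break
                if fixed:
                    changed = True
                    text = "".join(seq)
                    start = p
                else:
                    start = p + 1


def _safe_codons(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(SENSE_CODONS[rng.integers(0, len(SENSE_CODONS), n)])


@dataclass
class _Gene:
    """Blueprint shared between the two species' copies of one gene."""

    subject_id: str
    orf_len: int  # includes stop codon
    utr5_len: int
    utr3_len: int
    pas_class: Optional[str]  # DNA hexamer, "other:<hex>", or None
    pas_gap: int


def _build_transcript(
    rng: np.random.Generator,
    cfg: SynthConfig,
    gene: _Gene,
    defect: str,
) -> tuple[str, dict]:
    """Assemble one transcript instance; returns (sequence, truth fields)."""
    n_codons = gene.orf_len // 3
    # ORF: ATG + interior sense codons + stop; first interior codon's first
    # base carries the +4 Kozak position
    stop = "TAG" if defect == "internal_polya" else ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    plus4 = _draw_pwm_base(rng, cfg.kozak_pwm[4])
    while True:
        codon2 = plus4 + _rand_bases(rng, 2)
        if codon2 not in STOP_CODONS:
            break
    interior = _safe_codons(rng, n_codons - 3)
    orf = "ATG" + codon2 + interior + stop

    # 5'UTR with Kozak -4..-1 and no in-frame ATG
    L5 = gene.utr5_len
    utr5 = list(_rand_bases(rng, L5))
    if L5 >= 4:
        for k, pos in enumerate((-4, -3, -2, -1)):
            utr5[L5 - 4 + k] = _draw_pwm_base(rng, cfg.kozak_pwm[pos])
    _scrub_inframe_atg(utr5, rng)
    utr5 = "".join(utr5)

    truth: dict = {}
    if defect == "missing_stop":
        # open reading through the 3' end: 3'UTR continues in sense codons
        orf = orf[:-3] + _safe_codons(rng, 1)
        utr3 = _safe_codons(rng, max(2, gene.utr3_len // 3))
        tail_len = rng.integers(*cfg.tail_len_range)
        seq = utr5 + orf + utr3 + "A" * tail_len
        truth.update(pas_class="none", pas_hexamer="", pas_offset=-1,
                     tail_len=int(tail_len))
        return seq, truth

    if defect == "internal_polya":
        g = int(rng.integers(4, 10))  # 3'UTR shorter than the suspect cutoff
        utr3 = _rand_bases(rng, g, NON_A)
        tail_len = int(rng.integers(12, min(9 * g, cfg.tail_len_range[1]) + 1))
        seq_list = list(utr5 + orf + utr3)
        _scrub_canonicals(
            seq_list, len(seq_list) - 47, len(seq_list), range(0, 0), rng,
            codon_frame_anchor=len(utr5),
        )
        seq = "".join(seq_list) + "A" * tail_len
        truth.update(pas_class="none", pas_hexamer="", pas_offset=-1,
                     tail_len=tail_len)
        return seq, truth

    # regular 3'UTR with planted PAS (or no PAS for missing_polya decoys)
    L3 = gene.utr3_len
    if defect == "missing_polya":
        utr3 = list(_rand_bases(rng, L3))
        utr3[-1] = "C"
        # keep the 3' end un-taillike
        for q in range(max(0, L3 - 12), L3):
            if utr3[q] == "A" and rng.random() < 0.5:
                utr3[q] = str(NON_A[rng.integers(0, 3)])
        seq = utr5 + orf + "".join(utr3)
        truth.update(pas_class="none", pas_hexamer="", pas_offset=-1, tail_len=0)
        return seq, truth

    g = gene.pas_gap
    hexamer = gene.pas_class if gene.pas_class not in (None,) else None
    assert hexamer is not None
    planted = hexamer.split(":")[1] if hexamer.startswith("other:") else hexamer
    body = _rand_bases(rng, L3 - 6 - g)
    gap = _rand_bases(rng, g, NON_A)
    utr3 = list(body + planted + gap)
    protected = range(len(body), len(body) + 6)
    full = list(utr5 + orf) + utr3
    offset_in_seq = len(utr5) + len(orf)
    _scrub_canonicals(
        full, len(full) - 47, len(full),
        range(offset_in_seq + protected.start, offset_in_seq + protected.stop),
        rng,
        codon_frame_anchor=len(utr5),
    )
    tail_len = int(rng.integers(*cfg.tail_len_range))
    seq = "".join(full) + "A" * tail_len
    if hexamer.startswith("other:"):
        truth.update(pas_class="other", pas_hexamer=to_rna(planted))
    else:
        truth.update(pas_class=to_rna(planted), pas_hexamer=to_rna(planted))
    truth.update(pas_offset=g, tail_len=tail_len)
    return seq, truth


def _mutate_instance(
    rng: np.random.Generator,
    cfg: SynthConfig,
    gene: _Gene,
    seq_a: str,
    truth_a: dict,
) -> str:
    """Derive the species-B ortholog copy from the species-A sequence:
    per-region substitution with the ORF start/stop and the planted PAS
    hexamer + gap protected, stop codons never created, and the 5'UTR
    re-scrubbed of in-frame ATGs."""
    L5, Lorf, L3 = gene.utr5_len, gene.orf_len, gene.utr3_len
    tail_len = truth_a["tail_len"]
    utr5 = list(seq_a[:L5])
    orf = list(seq_a[L5 : L5 + Lorf])
    utr3 = list(seq_a[L5 + Lorf : L5 + Lorf + L3])

    r = cfg.ortholog_divergence_utr
    for i in range(L5):
        if rng.random() < r:
            others = [b for b in "ACGT" if b != utr5[i]]
            utr5[i] = others[rng.integers(0, 3)]
    _scrub_inframe_atg(utr5, rng)

    r = cfg.ortholog_divergence_orf
    for c0 in range(3, Lorf - 3, 3):  # keep ATG and stop codon intact
        original = orf[c0 : c0 + 3]
        for k in range(3):
            if rng.random() < r:
                others = [b for b in "ACGT" if b != orf[c0 + k]]
                orf[c0 + k] = others[rng.integers(0, 3)]
        if "".join(orf[c0 : c0 + 3]) in STOP_CODONS:
            orf[c0 : c0 + 3] = original

    r = cfg.ortholog_divergence_utr
    protected_lo = L3 - 6 - gene.pas_gap  # hexamer + gap stay fixed
    for i in range(max(0, protected_lo)):
        if rng.random() < r:
            others = [b for b in "ACGT" if b != utr3[i]]
            utr3[i] = others[rng.integers(0, 3)]
    full = utr5 + orf + utr3
    planted = range(L5 + Lorf + protected_lo, L5 + Lorf + protected_lo + 6)
    _scrub_canonicals(full, len(full) - 47, len(full), planted, rng,
                      codon_frame_anchor=L5)
    tail_len_b = int(rng.integers(*cfg.tail_len_range))
    return "".join(full) + "A" * tail_len_b


def _hamming_identity(x: str, y: str) -> float:
    same = sum(1 for a, b in zip(x, y) if a == b)
    return 100.0 * same / len(x)


def simulate(config: SynthConfig) -> SimResult:
    """Generate the full two-species dataset; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    cfg = config

    # choose PAS class per gene
    classes = list(cfg.pas_freqs.items())
    other_frac = 1.0 - sum(cfg.pas_freqs.values())
    variant_names = list(VARIANT_HEXAMERS)
    variant_w = np.array([VARIANT_HEXAMERS[v] for v in variant_names], dtype=float)
    variant_w /= variant_w.sum()

    def draw_pas_class() -> str:
        u = rng.random()
        acc = 0.0
        for hexamer, f in classes:
            acc += f
            if u < acc:
                return hexamer
        v = variant_names[rng.choice(len(variant_names), p=variant_w)]
        return f"other:{v}"

    defect_names = list(cfg.defect_rates)
    defect_p = np.array([cfg.defect_rates[d] for d in defect_names], dtype=float)
    if defect_p.sum() > 1:
        raise ValueError("defect rates sum above 1")

    def draw_defect() -> str:
        u = rng.random()
        acc = 0.0
        for name, p in zip(defect_names, defect_p):
            acc += p
            if u < acc:
                return name
        return "none"

    records: dict[str, list[TranscriptRecord]] = {"A": [], "B": []}
    hits: list[AlignmentHit] = []
    rows: list[dict] = []
    pair_rows: list[dict] = []

    def emit_hit(tid: str, gene: _Gene, defect: str) -> None:
        if defect == "no_hit":
            return
        n_aligned = gene.orf_len // 3 - 1  # exclude stop codon
        if defect == "missing_start":
            s_start = 15
        else:
            s_start = 1
        q_start = gene.utr5_len + 1
        hits.append(
            AlignmentHit(
                query_id=tid,
                subject_id=gene.subject_id,
                evalue=float(10.0 ** rng.uniform(-50, -6)),
                q_start=q_start,
                q_end=q_start + 3 * n_aligned - 1,
                s_start=s_start,
                s_end=s_start + n_aligned - 1,
                frame=(q_start - 1) % 3 + 1,
                pct_identity=float(np.round(rng.uniform(85, 100), 1)),
            )
        )

    def truth_row(tid: str, species: str, gene: _Gene, seq: str, defect: str, t: dict) -> dict:
        L5 = gene.utr5_len
        expected = {
            "none": "full_length",
            "missing_polya": "missing_polyA",
            "missing_stop": "missing_stop",
            "internal_polya": "internal_polyA_suspect",
            "no_hit": "no_significant_hit",
            "missing_start": "missing_conserved_start",
        }[defect]
        tail_len = t["tail_len"]
        trimmed = len(seq) - tail_len
        has_orf = defect not in ("missing_stop", "missing_start")
        kozak = seq[L5 - 4 : L5 + 4] if (L5 >= 4 and has_orf) else ""
        return {
            "transcript_id": tid,
            "species": species,
            "gene_id": gene.subject_id,
            "status": expected,
            "orf_start": L5 + 1 if has_orf else -1,
            "orf_end": L5 + gene.orf_len if has_orf else -1,
            "utr5_len": L5,
            "utr3_len": trimmed - (L5 + gene.orf_len) if has_orf else -1,
            "tail_start": trimmed + 1 if tail_len else -1,
            "tail_len": tail_len,
            "pas_class": t["pas_class"],
            "pas_hexamer": t["pas_hexamer"],
            "pas_offset": t["pas_offset"],
            "kozak_context": kozak,
        }

    # ---- shared-identity genes: species A copy + mutated species B copy
    for g_idx in range(cfg.n_shared_identities):
        gene = _Gene(
            subject_id=f"SP{g_idx:05d}",
            orf_len=_draw_len(rng, cfg.orf_len_mu, cfg.orf_len_sigma, cfg.orf_len_clip, 3),
            utr5_len=(
                int(rng.integers(0, 4))
                if rng.random() < cfg.frac_short_utr5
                else _draw_len(rng, cfg.utr5_len_mu, cfg.utr5_len_sigma, cfg.utr5_len_clip)
            ),
            utr3_len=_draw_len(rng, cfg.utr3_len_mu, cfg.utr3_len_sigma, cfg.utr3_len_clip),
            pas_class=draw_pas_class(),
            pas_gap=int(rng.integers(*cfg.pas_gap_range)),
        )
        seq_a, t_a = _build_transcript(rng, cfg, gene, "none")
        tid_a, tid_b = f"A_{g_idx:05d}", f"B_{g_idx:05d}"
        seq_b = _mutate_instance(rng, cfg, gene, seq_a, t_a)
        t_b = dict(t_a)
        t_b["tail_len"] = len(seq_b) - (len(seq_a) - t_a["tail_len"])
        records["A"].append(TranscriptRecord(tid_a, seq_a, species="A"))
        records["B"].append(TranscriptRecord(tid_b, seq_b, species="B"))
        emit_hit(tid_a, gene, "none")
        emit_hit(tid_b, gene, "none")
        rows.append(truth_row(tid_a, "A", gene, seq_a, "none", t_a))
        rows.append(truth_row(tid_b, "B", gene, seq_b, "none", t_b))
        L5, Lorf, L3 = gene.utr5_len, gene.orf_len, gene.utr3_len
        pair_rows.append(
            {
                "gene_id": gene.subject_id,
                "id_A": tid_a,
                "id_B": tid_b,
                "orf_identity": _hamming_identity(
                    seq_a[L5 : L5 + Lorf], seq_b[L5 : L5 + Lorf]
                ),
                "utr3_identity": _hamming_identity(
                    seq_a[L5 + Lorf : L5 + Lorf + L3],
                    seq_b[L5 + Lorf : L5 + Lorf + L3],
                ),
            }
        )

    # ---- species-specific genes (defects drawn here)
    n_specific = cfg.n_transcripts - cfg.n_shared_identities
    subject_counter = cfg.n_shared_identities
    for species in ("A", "B"):
        for k in range(n_specific):
            defect = draw_defect()
            gene = _Gene(
                subject_id=f"SP{subject_counter:05d}",
                orf_len=_draw_len(rng, cfg.orf_len_mu, cfg.orf_len_sigma, cfg.orf_len_clip, 3),
                utr5_len=(
                    int(rng.integers(0, 4))
                    if rng.random() < cfg.frac_short_utr5
                    else _draw_len(rng, cfg.utr5_len_mu, cfg.utr5_len_sigma, cfg.utr5_len_clip)
                ),
                utr3_len=_draw_len(rng, cfg.utr3_len_mu, cfg.utr3_len_sigma, cfg.utr3_len_clip),
                pas_class=draw_pas_class(),
                pas_gap=int(rng.integers(*cfg.pas_gap_range)),
            )
            subject_counter += 1
            seq, t = _build_transcript(rng, cfg, gene, defect)
            tid = f"{species}_{cfg.n_shared_identities + k:05d}"
            records[species].append(TranscriptRecord(tid, seq, species=species))
            emit_hit(tid, gene, defect)
            rows.append(truth_row(tid, species, gene, seq, defect, t))

    # ---- paralog / allele triples
    triples: list[Triple] = []
    triple_rows: list[dict] = []
    for n, relation, d_within in (
        (cfg.n_allele_triples, "allele", cfg.allele_divergence),
        (cfg.n_paralog_triples, "paralog", cfg.paralog_divergence),
    ):
        for k in range(n):
            x1 = _rand_bases(rng, cfg.triple_len)
            x2 = mutate(x1, d_within, rng=rng)
            y = mutate(x1, cfg.species_divergence, rng=rng)
            tid = f"T_{relation}_{k:04d}"
            ids = (f"{tid}_X1", f"{tid}_X2", f"{tid}_Y")
            triples.append(Triple(tid, relation, ids, (x1, x2, y)))
            triple_rows.append(
                {"triple_id": tid, "relation": relation,
                 "id_x1": ids[0], "id_x2": ids[1], "id_y": ids[2]}
            )

    truth = TruthTable(
        transcripts=pd.DataFrame(rows),
        pairs=pd.DataFrame(
            pair_rows,
            columns=["gene_id", "id_A", "id_B", "orf_identity", "utr3_identity"],
        ),
        triples=pd.DataFrame(
            triple_rows,
            columns=["triple_id", "relation", "id_x1", "id_x2", "id_y"],
        ),
    )
    return SimResult(records=records, hits=hits, truth=truth, triples=triples, config=cfg)
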