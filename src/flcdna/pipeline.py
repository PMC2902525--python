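"""Pipeline orchestration and report assembly.

Chains the stages — classification, ORF/UTR characterization, PAS calling
and hexamer discovery, Kozak profiling, motif scanning, cross-species
comparison — over one or two species' FASTA + tabular-hit inputs, writing
stage TSVs and a run manifest into an output directory.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import cross_species, kozak, polyadenylation, transcript_features, utr_motifs
from .fullength import FullLengthCall, Status, classify_full_length
from .polyadenylation import PasClass
from .seq_io import TranscriptRecord, read_blast_tab, read_fasta

ALL_STAGES = ("classify", "characterize", "pas", "kozak", "motifs", "compare")


@dataclass
class PipelineConfig:
    fasta: list[str]  # one or more FASTA paths (species token in headers)
    hits: str
    outdir: str
    stages: tuple[str, ...] = ALL_STAGES
    e_cut: float = 1e-5
    max_subject_aa: int = 10
    min_utr3: int = 10
    min_tail: int = 10
    max_mismatch_frac: float = 0.1
    pas_window: int = 35
    min_support: int = 30
    bin_width_orf: int = 300
    bin_width_utr: int = 100
    species_token: str = "species"
    seed: int = 0


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    records: list[TranscriptRecord]
    calls: list[FullLengthCall]
    outdir: Path
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the requested stages; writes stage TSVs plus manifest.json."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for path in list(config.fasta) + [config.hits]:
        if not Path(path).exists():
            raise FileNotFoundError(path)

    records: list[TranscriptRecord] = []
    for path in config.fasta:
        records.extend(read_fasta(path, species_token=config.species_token))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids across input FASTA files")
    hits_by_query: dict[str, list] = {}
    for hit in read_blast_tab(config.hits):
        hits_by_query.setdefault(hit.query_id, []).append(hit)

    counts: dict[str, dict] = {"input_transcripts": len(records)}
    manifest = {
        "command": " ".join(sys.argv),
        "tool_version": _pkg_version("flcdna"),
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "input_checksums": {
            str(p): _sha256(str(p)) for p in list(config.fasta) + [config.hits]
        },
        "counts": counts,
    }

    polya = {
        r.id: polyadenylation.detect_polya(r, config.min_tail, config.max_mismatch_frac)
        for r in records
    }
    calls = [
        classify_full_length(
            r,
            hits_by_query.get(r.id, []),
            polya[r.id],
            min_utr3=config.min_utr3,
            e_cut=config.e_cut,
            max_subject_aa=config.max_subject_aa,
            pas_window_len=config.pas_window,
        )
        for r in records
    ]
    by_id = {r.id: r for r in records}

    if "classify" in config.stages:
        df = pd.DataFrame(
            {
                "transcript_id": [c.transcript_id for c in calls],
                "species": [by_id[c.transcript_id].species for c in calls],
                "status": [c.status.value for c in calls],
                "conserved_start_pos": [c.conserved_start_pos for c in calls],
                "subject_id": [c.best_hit_subject for c in calls],
                "evalue": [c.best_hit_evalue for c in calls],
            }
        )
        df.to_csv(outdir / "classification.tsv", sep="\t", index=False)
        status_counts = df["status"].value_counts().to_dict()
        counts["status"] = status_counts
        assert sum(status_counts.values()) == len(records)

    annotated = [(by_id[c.transcript_id], c.orf) for c in calls if c.orf is not None]

    if "characterize" in config.stages and annotated:
        annots = [orf for _, orf in annotated]
        pd.DataFrame(
            {
                "transcript_id": [a.transcript_id for a in annots],
                "orf_start": [a.orf_start for a in annots],
                "orf_end": [a.orf_end for a in annots],
                "orf_len": [a.orf_len for a in annots],
                "utr5_len": [a.utr5_len for a in annots],
                "utr3_len": [a.utr3_len for a in annots],
            }
        ).to_csv(outdir / "orf_annotation.tsv", sep="\t", index=False)
        summary = transcript_features.summarize(
            annots, config.bin_width_orf, config.bin_width_utr
        )
        pd.DataFrame(
            {
                "n": [summary.n],
                "mean_seq_len": [round(summary.mean_seq_len)],
                "mean_orf_len": [round(summary.mean_orf_len)],
                "mean_utr5_len": [round(summary.mean_utr5_len)],
                "mean_utr3_len": [round(summary.mean_utr3_len)],
                "min_orf_len": [summary.min_orf_len],
                "max_orf_len": [summary.max_orf_len],
            }
        ).to_csv(outdir / "length_summary.tsv", sep="\t", index=False)
        for name, hist in (("orf", summary.orf_hist), ("utr3", summary.utr3_hist)):
            pd.DataFrame(
                {"bin_start": list(hist), "count": list(hist.values())}
            ).to_csv(outdir / f"{name}_histogram.tsv", sep="\t", index=False)
        counts["annotated"] = len(annots)

    if "pas" in config.stages:
        tailed = [
            (by_id[c.transcript_id], polya[c.transcript_id])
            for c in calls
            if polya[c.transcript_id].has_tail
        ]
        pas_calls = [
            polyadenylation.scan_pas(r, p, config.pas_window) for r, p in tailed
        ]
        windows = [
            polyadenylation.pas_window(r, p, config.pas_window) for r, p in tailed
        ]
        noncanon = [
            w
            for pc, w in zip(pas_calls, windows)
            if pc.pas_class not in (PasClass.AAUAAA, PasClass.AUUAAA)
        ]
        table = polyadenylation.discover_hexamers(noncanon, config.min_support)
        polyadenylation.assign_discovered(
            pas_calls,
            windows,
            table,
        )
        pd.DataFrame(
            {
                "transcript_id": [p.transcript_id for p in pas_calls],
                "pas_class": [p.pas_class.value for p in pas_calls],
                "hexamer": [p.hexamer for p in pas_calls],
                "offset": [p.offset for p in pas_calls],
            }
        ).to_csv(outdir / "pas_calls.tsv", sep="\t", index=False)
        pd.DataFrame(table.rows(), columns=["hexamer", "n_transcripts"]).to_csv(
            outdir / "hexamer_table.tsv", sep="\t", index=False
        )
        counts["tailed_transcripts"] = len(tailed)
        counts["pas_classes"] = {
            cls.value: sum(1 for p in pas_calls if p.pas_class is cls)
            for cls in PasClass
        }

    if "kozak" in config.stages and annotated:
        contexts, excluded = kozak.extract_contexts(annotated)
        counts["kozak_contexts"] = len(contexts)
        counts["kozak_excluded"] = excluded
        if contexts:
            profile = kozak.build_profile(contexts)
            rows = []
            for i, pos in enumerate(kozak.POSITIONS):
                rows.append(
                    {
                        "position": pos,
                        "A": int(profile.counts[i, 0]),
                        "C": int(profile.counts[i, 1]),
                        "G": int(profile.counts[i, 2]),
                        "U": int(profile.counts[i, 3]),
                        "info_bits": round(float(profile.info_bits[i]), 4),
                    }
                )
            pd.DataFrame(rows).to_csv(outdir / "kozak_profile.tsv", sep="\t", index=False)
            counts["kozak_consensus"] = profile.consensus_rna

    if "motifs" in config.stages:
        hits_rows = []
        for rec, orf in annotated:
            utr5_seq = rec.seq[: orf.utr5_len]
            utr3_seq = rec.seq[orf.orf_end : orf.orf_end + orf.utr3_len]
            for desc in utr_motifs.BUILTIN_DESCRIPTORS.values():
                target = utr5_seq if desc.target_utr == "utr5" else utr3_seq
                if not target:
                    continue
                for h in utr_motifs.scan_motif(target, desc, rec.id):
                    hits_rows.append(
                        {
                            "transcript_id": h.transcript_id,
                            "motif": h.motif,
                            "utr": desc.target_utr,
                            "start": h.start,
                            "end": h.end,
                            "stem_mismatches": h.stem_mismatches,
                        }
                    )
        pd.DataFrame(
            hits_rows,
            columns=["transcript_id", "motif", "utr", "start", "end", "stem_mismatches"],
        ).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
        counts["motif_hits"] = len(hits_rows)

    if "compare" in config.stages:
        species = sorted({r.species for r in records})
        if len(species) == 2:
            sp_a, sp_b = species
            calls_a = [c for c in calls if by_id[c.transcript_id].species == sp_a]
            calls_b = [c for c in calls if by_id[c.transcript_id].species == sp_b]
            pairs = cross_species.pair_by_identity(calls_a, calls_b)
            orf_by_id = {c.transcript_id: c.orf for c in calls if c.orf is not None}
            computed = []
            for pair in pairs:
                orf_a, orf_b = orf_by_id.get(pair.id_a), orf_by_id.get(pair.id_b)
                if orf_a is None or orf_b is None:
                    continue
                cross_species.compare_pair_regions(
                    pair,
                    by_id[pair.id_a].seq,
                    by_id[pair.id_b].seq,
                    (orf_a.orf_start, orf_a.orf_end),
                    (orf_b.orf_start, orf_b.orf_end),
                    orf_a.trimmed_len,
                    orf_b.trimmed_len,
                )
                computed.append(pair)
            pd.DataFrame(
                [
                    {
                        "gene_id": p.gene_id,
                        "id_a": p.id_a,
                        "id_b": p.id_b,
                        "orf_identity": p.orf_identity,
                        "utr3_identity": p.utr3_identity,
                    }
                    for p in computed
                ],
                columns=["gene_id", "id_a", "id_b", "orf_identity", "utr3_identity"],
            ).to_csv(outdir / "ortholog_pairs.tsv", sep="\t", index=False)
            hist_rows = []
            for region in ("orf", "utr3"):
                hist, frac = cross_species.similarity_histogram(computed, region)
                for b, c in hist.items():
                    hist_rows.append({"region": region, "identity": b, "count": c})
                counts[f"frac_98_99_{region}"] = round(frac, 4)
            pd.DataFrame(hist_rows).to_csv(
                outdir / "similarity_histogram.tsv", sep="\t", index=False
            )
            counts["ortholog_pairs"] = len(computed)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return PipelineResult(records=records, calls=calls, outdir=outdir, manifest=manifest)
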