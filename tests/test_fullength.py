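"""Conserved-start rule and four-part full-length classification."""

import numpy as np
import pytest

from flcdna._util import STOP_CODONS
from flcdna.fullength import (
    Status,
    classify_full_length,
    has_conserved_start,
    select_best_hit,
)
from flcdna.polyadenylation import detect_polya
from flcdna.seq_io import AlignmentHit, TranscriptRecord

from conftest import hits_by_query


def _hit(qid="t", sid="s", evalue=1e-12, q_start=1, n_aa=10, s_start=1, pident=95.0):
    return AlignmentHit(
        query_id=qid,
        subject_id=sid,
        evalue=evalue,
        q_start=q_start,
        q_end=q_start + 3 * n_aa - 1,
        s_start=s_start,
        s_end=s_start + n_aa - 1,
        frame=(q_start - 1) % 3 + 1,
        pct_identity=pident,
    )


class TestSelectBestHit:
    def test_minimum_evalue_wins(self):
        hits = [_hit(evalue=1e-3), _hit(sid="s2", evalue=1e-12)]
        assert select_best_hit(hits).subject_id == "s2"

    def test_threshold_is_strict_and_excludes_weak_hits(self):
        assert select_best_hit([_hit(evalue=1e-4)]) is None
        assert select_best_hit([_hit(evalue=1e-5)]) is None  # boundary: not < cut
        assert select_best_hit([_hit(evalue=9e-6)]) is not None

    def test_ties_broken_by_identity_then_subject(self):
        hits = [
            _hit(sid="sB", evalue=1e-12, pident=90.0),
            _hit(sid="sA", evalue=1e-12, pident=95.0),
        ]
        assert select_best_hit(hits).subject_id == "sA"
        hits = [
            _hit(sid="sB", evalue=1e-12, pident=95.0),
            _hit(sid="sA", evalue=1e-12, pident=95.0),
        ]
        assert select_best_hit(hits).subject_id == "sA"

    def test_mixed_query_ids_rejected(self):
        with pytest.raises(ValueError):
            select_best_hit([_hit(qid="a"), _hit(qid="b")])


class TestConservedStart:
    def test_atg_at_alignment_start_with_subject_start_one(self):
        seq = "ATG" + "GCT" * 9 + "TAA"
        rec = TranscriptRecord("t", seq)
        found, pos = has_conserved_start(rec, _hit(q_start=1, s_start=1))
        assert (found, pos) == (True, 1)

    def test_upstream_in_frame_atg_without_intervening_stop(self):
        # ATG 12 nt upstream of alignment start, alignment starts at aa 15
        seq = "C" + "ATG" + "GCTGCAGCC" + "GCA" * 10 + "TAA"
        rec = TranscriptRecord("t", seq)
        found, pos = has_conserved_start(rec, _hit(q_start=14, s_start=15))
        assert (found, pos) == (True, 2)

    def test_intervening_stop_disqualifies_upstream_atg(self):
        seq = "C" + "ATG" + "TAAGCAGCC" + "GCA" * 10 + "TAA"
        rec = TranscriptRecord("t", seq)
        found, pos = has_conserved_start(rec, _hit(q_start=14, s_start=15))
        assert found is False and pos is None

    def test_atg_beyond_ten_aa_window_rejected(self):
        # first in-frame ATG maps to subject aa 12; nothing upstream
        seq = "GCC" * 11 + "ATG" + "GCA" * 8
        rec = TranscriptRecord("t", seq)
        found, pos = has_conserved_start(rec, _hit(q_start=1, s_start=1, n_aa=20))
        assert found is False

    def test_within_window_atg_accepted(self):
        # ATG maps to subject aa 10 exactly (inclusive window)
        seq = "GCC" * 9 + "ATG" + "GCA" * 10
        rec = TranscriptRecord("t", seq)
        found, pos = has_conserved_start(rec, _hit(q_start=1, s_start=1, n_aa=20))
        assert (found, pos) == (True, 28)

    def test_brute_force_oracle_on_random_records(self, rng):
        """Exhaustive scan over every in-frame codon reproduces the rule."""
        bases = np.array(list("ACGT"))

        def oracle(seq, hit, max_aa=10):
            frame0 = (hit.q_start - 1) % 3
            q0 = hit.q_start - 1
            cands = []
            for p in range(frame0, len(seq) - 2, 3):
                if seq[p : p + 3] != "ATG":
                    continue
                if p < q0:
                    between = [seq[k : k + 3] for k in range(p + 3, q0, 3)]
                    if not any(c in STOP_CODONS for c in between):
                        cands.append(p)
                elif q0 <= p <= hit.q_end - 3:
                    aa = hit.s_start + (p - q0) // 3
                    if aa <= max_aa:
                        cands.append(p)
            return (True, min(cands) + 1) if cands else (False, None)

        for _ in range(300):
            n = int(rng.integers(60, 200))
            seq = "".join(bases[rng.integers(0, 4, n)])
            rec = TranscriptRecord("t", seq)
            q_start = int(rng.integers(1, n - 32))
            n_aa = int(rng.integers(3, (n - q_start + 1) // 3 + 1))
            s_start = int(rng.integers(1, 16))
            hit = _hit(q_start=q_start, n_aa=n_aa, s_start=s_start)
            assert has_conserved_start(rec, hit) == oracle(seq, hit)


class TestClassification:
    def _full_length_record(self):
        seq = "CCCC" + "ATG" + "GCA" * 20 + "TAA" + "C" * 40 + "AATAAA" + "CGT" * 4 + "A" * 20
        rec = TranscriptRecord("t", seq)
        hit = _hit(qid="t", q_start=5, n_aa=20, s_start=1)
        return rec, [hit]

    def test_all_criteria_met(self):
        rec, hits = self._full_length_record()
        call = classify_full_length(rec, hits, detect_polya(rec))
        assert call.status is Status.FULL_LENGTH
        assert call.conserved_start_pos == 5

    def test_short_utr3_without_pas_is_internal_polya_suspect(self):
        seq = "CCCC" + "ATG" + "GCA" * 20 + "TAA" + "CGTC" + "A" * 20
        rec = TranscriptRecord("t", seq)
        call = classify_full_length(rec, [_hit(qid="t", q_start=5, n_aa=20)], detect_polya(rec))
        assert call.status is Status.INTERNAL_POLYA_SUSPECT

    def test_short_utr3_with_pas_stays_full_length(self):
        seq = "CCCC" + "ATG" + "GCA" * 20 + "AATAAA" * 2 + "TAA" + "CGTC" + "A" * 20
        # place the PAS upstream of the stop so it falls in the 35-nt window
        rec = TranscriptRecord("t", seq)
        call = classify_full_length(rec, [_hit(qid="t", q_start=5, n_aa=20)], detect_polya(rec))
        assert call.status is Status.FULL_LENGTH

    def test_gate_order_no_hit_first(self):
        rec, hits = self._full_length_record()
        weak = [_hit(qid="t", q_start=5, n_aa=20, evalue=1e-3)]
        assert classify_full_length(rec, weak, detect_polya(rec)).status is Status.NO_SIGNIFICANT_HIT
        assert classify_full_length(rec, [], detect_polya(rec)).status is Status.NO_SIGNIFICANT_HIT

    def test_missing_polya(self):
        seq = "CCCC" + "ATG" + "GCA" * 20 + "TAA" + "CGT" * 20
        rec = TranscriptRecord("t", seq)
        call = classify_full_length(rec, [_hit(qid="t", q_start=5, n_aa=20)], detect_polya(rec))
        assert call.status is Status.MISSING_POLYA

    def test_determinism(self, defect_sim):
        hits = hits_by_query(defect_sim)
        for rec in defect_sim.records["A"][:20]:
            polya = detect_polya(rec)
            first = classify_full_length(rec, hits.get(rec.id, []), polya)
            second = classify_full_length(rec, hits.get(rec.id, []), polya)
            assert first.status == second.status
            assert first.conserved_start_pos == second.conserved_start_pos

    def test_confusion_matrix_matches_simulated_truth(self, defect_sim):
        """Every planted defect class is recovered exactly."""
        truth = defect_sim.truth.transcripts.set_index("transcript_id")["status"]
        hits = hits_by_query(defect_sim)
        for species in ("A", "B"):
            for rec in defect_sim.records[species]:
                call = classify_full_length(rec, hits.get(rec.id, []), detect_polya(rec))
                assert call.status.value == truth[rec.id], rec.id

    def test_relaxing_ecut_preserves_full_length(self, clean_sim):
        """A weaker threshold only adds hits: full-length calls persist."""
        hits = hits_by_query(clean_sim)
        for rec in clean_sim.records["A"][:30]:
            polya = detect_polya(rec)
            strict = classify_full_length(rec, hits.get(rec.id, []), polya, e_cut=1e-5)
            relaxed = classify_full_length(rec, hits.get(rec.id, []), polya, e_cut=1e-2)
            if strict.status is Status.FULL_LENGTH:
                assert relaxed.status is Status.FULL_LENGTH
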