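"""Format readers/writers: round trips, coordinate conventions, validation."""

import numpy as np
import pandas as pd
import pytest

from nelfyap import dataio
from nelfyap.dataio import (
    ClinicalRecord,
    DataValidationError,
    GeneSetCollection,
    SignalTrack,
    TranscriptModel,
)


class TestCounts:
    def test_round_trip(self, tiny_matrix, tmp_path):
        cp, sp = tmp_path / "c.tsv", tmp_path / "s.csv"
        dataio.write_counts(tiny_matrix, cp, sp)
        back = dataio.read_counts(cp, sp)
        pd.testing.assert_frame_equal(back.counts, tiny_matrix.counts)
        assert list(back.samples["condition"]) == list(tiny_matrix.samples["condition"])

    def test_sheet_sample_missing_from_matrix(self, tiny_matrix, tmp_path):
        cp, sp = tmp_path / "c.tsv", tmp_path / "s.csv"
        dataio.write_counts(tiny_matrix, cp, sp)
        sheet = pd.read_csv(sp)
        sheet.loc[len(sheet)] = ["S13", "siControl", 4]
        sheet.to_csv(sp, index=False)
        with pytest.raises(DataValidationError, match="sample missing"):
            dataio.read_counts(cp, sp)

    def test_negative_count_rejected(self, tiny_matrix, tmp_path):
        cp, sp = tmp_path / "c.tsv", tmp_path / "s.csv"
        m = tiny_matrix
        m.counts.iloc[0, 0] = 5  # keep valid for write
        dataio.write_counts(m, cp, sp)
        text = cp.read_text().replace("\t5\t", "\t-2\t", 1)
        cp.write_text(text)
        with pytest.raises(DataValidationError, match="negative count"):
            dataio.read_counts(cp, sp)

    def test_unknown_condition_rejected(self, tiny_matrix, tmp_path):
        cp, sp = tmp_path / "c.tsv", tmp_path / "s.csv"
        dataio.write_counts(tiny_matrix, cp, sp)
        sheet = pd.read_csv(sp)
        sheet.loc[0, "condition"] = "siFOO"
        sheet.to_csv(sp, index=False)
        with pytest.raises(DataValidationError, match="unknown condition"):
            dataio.read_counts(cp, sp)


class TestTranscripts:
    def test_gtf_coordinates_converted_to_half_open(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tsrc\ttranscript\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        (rec,) = dataio.read_transcripts(p)
        assert (rec.start, rec.end, rec.length, rec.strand) == (100, 200, 100, "+")

    def test_bed6_is_native_convention(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tg1|t1\t0\t-\n")
        (rec,) = dataio.read_transcripts(p)
        assert (rec.start, rec.end, rec.strand, rec.gene_id) == (100, 200, "-", "g1")

    def test_gtf_bed_round_trip_identity(self, tmp_path):
        orig = [
            TranscriptModel("chr1", 100, 600, "+", "g1", "t1"),
            TranscriptModel("chr2", 50, 950, "-", "g2", "t2"),
        ]
        p = tmp_path / "x.bed"
        dataio.write_transcripts_bed(orig, p)
        assert dataio.read_transcripts(p) == orig

    @pytest.mark.parametrize(
        "line",
        [
            'chr1\tsrc\ttranscript\t300\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";',
            'chr1\tsrc\ttranscript\t100\t200\t.\t?\t.\tgene_id "g"; transcript_id "t";',
            "chr1\tsrc\ttranscript\t100\t200\t.\t+\t.\tno attributes here",
        ],
    )
    def test_malformed_gtf_rejected(self, tmp_path, line):
        p = tmp_path / "bad.gtf"
        p.write_text(line + "\n")
        with pytest.raises(DataValidationError):
            dataio.read_transcripts(p)


class TestSignalTrack:
    def test_single_interval_mean(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t0\t100\t2.0\n")
        track = dataio.read_track(p)
        assert track.mean("chr1", 0, 100) == pytest.approx(2.0)

    def test_uncovered_bases_count_as_zero_in_mean(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t0\t100\t2.0\n")
        track = dataio.read_track(p)
        # [150,250) is entirely uncovered; [50,150) is half covered
        assert track.mean("chr1", 150, 250) == 0.0
        assert track.mean("chr1", 50, 150) == pytest.approx(1.0)

    def test_overlapping_intervals_rejected(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t0\t50\t1.0\nchr1\t25\t75\t3.0\n")
        with pytest.raises(DataValidationError, match="overlapping"):
            dataio.read_track(p)

    def test_unsorted_input_sorted_internally(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t50\t100\t3.0\nchr1\t0\t50\t1.0\n")
        track = dataio.read_track(p)
        assert track.mean("chr1", 0, 100) == pytest.approx(2.0)

    def test_round_trip_values(self, tmp_path):
        t = SignalTrack(
            {"chr1": (np.array([0, 100]), np.array([50, 180]), np.array([1.25, 0.5]))}
        )
        p = tmp_path / "t.bedGraph"
        dataio.write_track(t, p)
        back = dataio.read_track(p)
        for s, e in [(0, 50), (100, 180), (0, 200)]:
            assert back.mean("chr1", s, e) == pytest.approx(t.mean("chr1", s, e), abs=1e-9)


class TestGeneSets:
    def test_duplicate_members_collapsed(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\tg1\tg2\tg2\n")
        gsc = dataio.read_gene_sets(p)
        assert gsc.sets["S1"] == frozenset({"g1", "g2"})

    def test_duplicate_set_name_rejected(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\td\tg1\nS1\td\tg2\n")
        with pytest.raises(DataValidationError, match="duplicate set name"):
            dataio.read_gene_sets(p)

    def test_56_member_signature_round_trips(self, tmp_path):
        members = frozenset(f"YT{i:02d}" for i in range(56))
        gsc = GeneSetCollection({"YAP_signature": members})
        p = tmp_path / "s.gmt"
        dataio.write_gene_sets(gsc, p)
        back = dataio.read_gene_sets(p)
        assert len(back.sets["YAP_signature"]) == 56
        assert back.sets["YAP_signature"] == members

    def test_collapse_duplicate_scores_policies(self):
        genes = ["a", "b", "a", "c"]
        scores = [1.0, 2.0, -3.0, 0.5]
        g, s = dataio.collapse_gene_scores(genes, scores, policy="max_abs")
        assert dict(zip(g, s)) == {"b": 2.0, "a": -3.0, "c": 0.5}
        g, s = dataio.collapse_gene_scores(genes, scores, policy="drop")
        assert dict(zip(g, s)) == {"b": 2.0, "c": 0.5}


class TestClinical:
    def _record(self, **kw):
        base = dict(
            patient_id="p1", subtype="TNBC", yap_percent=80.0, nelfa_percent=5.0,
            yap_intensity=3, nelfa_intensity=1, os_months=30.0, dfs_months=25.0,
            os_event=0, dfs_event=1,
        )
        base.update(kw)
        return ClinicalRecord(**base)

    def test_valid_record(self):
        r = self._record()
        assert r.subtype == "TNBC" and r.yap_intensity == 3

    @pytest.mark.parametrize(
        "kw", [{"yap_intensity": 4}, {"yap_percent": 120.0}, {"os_months": -1.0},
               {"dfs_event": 2}, {"subtype": "luminal"}]
    )
    def test_invalid_records_rejected(self, kw):
        with pytest.raises(DataValidationError):
            self._record(**kw)

    def test_round_trip_and_blank_event_rejected(self, tmp_path):
        recs = [self._record(), self._record(patient_id="p2", covariates={"grade": "III"})]
        p = tmp_path / "c.csv"
        dataio.write_clinical(recs, p)
        back = dataio.read_clinical(p)
        assert [r.patient_id for r in back] == ["p1", "p2"]
        assert back[1].covariates["grade"] == "III"
        df = pd.read_csv(p)
        df.loc[0, "dfs_event"] = np.nan
        df.to_csv(p, index=False)
        with pytest.raises(DataValidationError, match="event required"):
            dataio.read_clinical(p)
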