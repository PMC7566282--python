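import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tuatlas import core_io
from tuatlas.core_io import (
    EndCoverageTrack,
    GeneRecord,
    ParseError,
    SiteCall,
    TerminatorPrediction,
    ValidationError,
    bed_score,
    downstream,
    upstream,
)


class TestEndCoverageIO:
    def test_bedgraph_interval_expands_to_per_base(self, tmp_path):
        # bedGraph is 0-based half-open: "chr 9 12 5" covers 1-based 10..12
        (tmp_path / "p.bg").write_text("chr\t9\t12\t5\n")
        (tmp_path / "m.bg").write_text("")
        track = core_io.read_end_coverage(
            (tmp_path / "p.bg", tmp_path / "m.bg"), "bedgraph_pair",
            {"library_id": "x"}, {"chr": 20},
        )
        arr = track.get("chr", "+")
        assert arr[9] == arr[10] == arr[11] == 5
        assert arr.sum() == 15

    def test_per_base_depth_is_identity(self, tmp_path):
        (tmp_path / "p.txt").write_text("chr\t7\t3\n")
        (tmp_path / "m.txt").write_text("chr\t2\t4\n")
        track = core_io.read_end_coverage(
            (tmp_path / "p.txt", tmp_path / "m.txt"), "per_base_depth",
            {"library_id": "x"}, {"chr": 10},
        )
        assert track.get("chr", "+")[6] == 3
        assert track.get("chr", "-")[1] == 4

    @pytest.mark.parametrize("bad", ["chr\t5\t-1\n", "chr\tfive\t3\n", "chr\t3\n"])
    def test_malformed_or_negative_lines_rejected(self, tmp_path, bad):
        (tmp_path / "p.txt").write_text(bad)
        (tmp_path / "m.txt").write_text("")
        with pytest.raises((ParseError, ValidationError)):
            core_io.read_end_coverage(
                (tmp_path / "p.txt", tmp_path / "m.txt"), "per_base_depth",
                {"library_id": "x"}, {"chr": 10},
            )

    @settings(max_examples=25, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(1, 50), st.integers(0, 30)), max_size=20
        ),
        dialect=st.sampled_from(["bedgraph_pair", "per_base_depth"]),
    )
    def test_write_then_read_round_trip(self, tmp_path_factory, data, dialect):
        tmp = tmp_path_factory.mktemp("rt")
        track = EndCoverageTrack("x", "c", "r", "termseq", {"chr": 50})
        for pos, val in data:
            track.set_count("chr", "+" if pos % 2 else "-", pos, val)
        core_io.write_end_coverage(track, tmp / "p", tmp / "m", dialect)
        back = core_io.read_end_coverage(
            (tmp / "p", tmp / "m"), dialect, {"library_id": "x",
            "library_kind": "termseq"}, {"chr": 50},
        )
        assert back == track


class TestGeneAnnotations:
    GFF = (
        "##gff-version 3\n"
        "chr\tsrc\tgene\t100\t400\t.\t+\t.\tID=g1\n"
        "chr\tsrc\tgene\t500\t900\t.\t-\t.\tID=g2\n"
        "chr\tsrc\ttRNA\t950\t1030\t.\t+\t.\tID=t1\n"
    )

    def test_start_codon_is_strand_aware(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(self.GFF)
        genes = {g.gene_id: g for g in core_io.read_gene_annotations(p)}
        assert genes["g1"].start_codon_pos == 100
        assert genes["g2"].start_codon_pos == 900
        assert genes["t1"].feature_class == "tRNA"

    def test_unknown_strand_rejected(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("chr\tsrc\tgene\t1\t10\t.\t*\t.\tID=g\n")
        with pytest.raises(ValidationError):
            core_io.read_gene_annotations(p)

    def test_bed_like_tsv_dialect(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "gene_id\treplicon_id\tstart\tend\tstrand\tfeature_class\n"
            "gA\tchr\t10\t90\t-\tprotein_coding\n"
        )
        (g,) = core_io.read_gene_annotations(p, format="bed_like_tsv")
        assert (g.start, g.end, g.strand, g.start_codon_pos) == (10, 90, "-", 90)


class TestTransTermOutput:
    REPORT = (
        "SEQUENCE chr (length 5000)\n"
        "  TERM 1          346 - 365      + G   100  -11.5 -4.9\n"
        "    CGCCAGCCGGC GCGGGGC TGCC GCCCCGC TTTTTTTATTTCTG\n"
        "  TERM 2         1200 - 1220     - F    77   -9.1 -3.2\n"
        "  TERM 3         2000 - 2024     + F    90  -13.0 -5.0\n"
    )

    def test_report_parse_yields_all_records(self, tmp_path):
        p = tmp_path / "t.tt"
        p.write_text(self.REPORT)
        preds = core_io.read_transterm_output(p)
        assert len(preds) == 3
        assert preds[0].hairpin_start == 346 and preds[0].hairpin_end == 365
        assert preds[0].stem_len == 7 and preds[0].loop_len == 4
        assert preds[1].strand == "-"

    def test_minus_strand_tail_is_reverse_complement_upstream_flank(self, toy_genome):
        # on -, the 3' flank is genomic hairpin_start-12 .. hairpin_start-1,
        # reverse-complemented
        pred = TerminatorPrediction("t1", "chr", "-", 30, 45, confidence=50)
        tail = core_io._tail_seq(pred, toy_genome)
        expect = toy_genome["chr"].subseq(18, 29, "-")
        assert tail == expect and len(tail) == 12

    def test_missing_confidence_is_parse_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "terminator_id\treplicon_id\tstrand\thairpin_start\thairpin_end\tconfidence\n"
            "t1\tchr\t+\t10\t30\t\n"
        )
        with pytest.raises(ParseError):
            core_io.read_transterm_output(p)

    def test_tsv_round_trip(self, tmp_path):
        preds = [
            TerminatorPrediction("t1", "chr", "+", 10, 30, 95, 8, 4, "TTTTTTTTACGT")
        ]
        core_io.write_terminator_tsv(preds, tmp_path / "t.tsv")
        back = core_io.read_transterm_output(tmp_path / "t.tsv")
        assert back[0].hairpin_start == 10 and back[0].confidence == 95


class TestSiteCatalog:
    def test_bed6_single_base_convention_and_score(self, tmp_path):
        sites = [
            SiteCall("chr", 100, "+", "tts", p_value=0.001, fdr=0.05)
        ]
        core_io.write_site_catalog(sites, tmp_path / "s.bed", format="bed6")
        line = (tmp_path / "s.bed").read_text().splitlines()[1]
        chrom, start, end, name, score, strand = line.split("\t")
        # -10*log10(0.05) = 13.01 -> 13
        assert (chrom, start, end, score, strand) == ("chr", "99", "100", "13", "+")

    def test_empty_catalog_writes_header_only(self, tmp_path):
        core_io.write_site_catalog([], tmp_path / "s.tsv", format="tsv")
        lines = (tmp_path / "s.tsv").read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("replicon_id")

    def test_tsv_round_trip_preserves_fields(self, tmp_path):
        sites = [
            SiteCall("chr", 5, "-", "tss_primary", 1e-8, 1e-6, 42.5,
                     frozenset({"c1", "c2"})),
            SiteCall("chr", 9, "+", "processing", 0.01, 0.04, 7.0),
        ]
        core_io.write_site_catalog(sites, tmp_path / "s.tsv")
        back = core_io.read_site_catalog(tmp_path / "s.tsv")
        assert back == sorted(sites, key=lambda s: s.position)

    def test_bed_score_caps_at_1000(self):
        assert bed_score(0.0) == 1000
        assert bed_score(1e-200) == 1000
        assert bed_score(1.0) == 0


class TestConventions:
    def test_downstream_upstream_are_strand_aware(self):
        assert downstream(100, "+") == 101
        assert downstream(100, "-") == 99
        assert upstream(100, "+") == 99
        assert upstream(100, "-") == 101

    def test_genome_rejects_ambiguity_codes_other_than_n(self):
        with pytest.raises(ValidationError):
            core_io.GenomeSequence("chr", "ACGTRY")
        g = core_io.GenomeSequence("chr", "ACGTN")
        assert g.length == 5

    def test_minus_strand_subseq_reverse_complements(self):
        g = core_io.GenomeSequence("chr", "AACGTT")
        assert g.subseq(1, 4, "-") == "CGTT"
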