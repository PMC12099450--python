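"""Transcript model, marker and element-library loading."""

import pytest

from amplisplice.errors import ConfigError, ParseError
from amplisplice.models_io import (
    Amplicon,
    TranscriptModel,
    VariantMarker,
    load_element_library,
    load_markers,
    load_transcript_model,
    write_bed12,
    write_markers,
)

PLUS = TranscriptModel(
    gene_symbol="G",
    transcript_id="TX.1",
    chrom="chr1",
    strand="+",
    exons=((100, 200), (300, 400), (500, 650)),
)
MINUS = TranscriptModel(
    gene_symbol="G",
    transcript_id="TX.2",
    chrom="chr1",
    strand="-",
    exons=((100, 200), (300, 400), (500, 650)),
)


class TestTranscriptModel:
    def test_plus_strand_numbering_is_genomic_order(self):
        assert PLUS.exon(1) == (100, 200)
        assert PLUS.exon(3) == (500, 650)

    def test_minus_strand_exon_one_is_rightmost(self):
        assert MINUS.exon(1) == (500, 650)
        assert MINUS.exon(3) == (100, 200)

    @pytest.mark.parametrize("model", [PLUS, MINUS])
    def test_numbering_genomic_bijection(self, model):
        numbers = {model.exon_number(i) for i in range(model.n_exons)}
        assert numbers == set(range(1, model.n_exons + 1))
        for n in numbers:
            iv = model.exon(n)
            idx = model.exons.index(iv)
            assert model.exon_number(idx) == n

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            TranscriptModel(
                gene_symbol="G", transcript_id="T", chrom="c", strand="+",
                exons=((0, 100), (50, 150)),
            )

    def test_single_exon_rejected(self):
        with pytest.raises(ConfigError):
            TranscriptModel(
                gene_symbol="G", transcript_id="T", chrom="c", strand="+",
                exons=((0, 100),),
            )

    def test_canonical_junctions(self):
        assert PLUS.canonical_junctions() == ((200, 300), (400, 500))


class TestBed12:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "m.bed"
        write_bed12(PLUS, path)
        again = load_transcript_model(path, "BED12", "TX.1")
        assert again == PLUS

    def test_minus_round_trip(self, tmp_path):
        path = tmp_path / "m.bed"
        write_bed12(MINUS, path)
        again = load_transcript_model(path, "BED12", "TX.2")
        assert again == MINUS
        assert again.exon(1) == (500, 650)

    def test_unsorted_block_starts_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text(
            "chr1\t100\t650\tT\t0\t+\t100\t100\t0\t2\t100,100\t300,0\n"
        )
        with pytest.raises(ParseError, match="not sorted"):
            load_transcript_model(path, "BED12")

    def test_parse_error_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\n")
        with pytest.raises(ParseError, match=":1"):
            load_transcript_model(path, "BED12")


class TestGff3:
    def test_minus_strand_exon_one_rightmost(self, tmp_path):
        path = tmp_path / "m.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\ttranscript\t101\t650\t.\t-\t.\tID=TX.2;gene=G\n"
            "chr1\tsrc\texon\t501\t650\t.\t-\t.\tParent=TX.2\n"
            "chr1\tsrc\texon\t101\t200\t.\t-\t.\tParent=TX.2\n"
            "chr1\tsrc\texon\t301\t400\t.\t-\t.\tParent=TX.2\n"
        )
        model = load_transcript_model(path, "GFF3", "TX.2")
        assert model.exons == ((100, 200), (300, 400), (500, 650))
        assert model.exon(1) == (500, 650)

    def test_unknown_transcript(self, tmp_path):
        path = tmp_path / "m.gff3"
        path.write_text("chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=OTHER\n")
        with pytest.raises(ParseError, match="TX.9"):
            load_transcript_model(path, "GFF3", "TX.9")


class TestMarkers:
    AMP = Amplicon(model=PLUS, first_exon=1, last_exon=3)

    def test_snv_inside_amplicon_retained_and_zero_based(self, tmp_path):
        path = tmp_path / "mk.tsv"
        path.write_text("chr1\t151\tv1\tG\tA\tALLELES=a2|a1\n")
        markers = load_markers(path, self.AMP)
        assert len(markers) == 1
        assert markers[0].pos == 150
        assert markers[0].allele_label_alt == "a1"

    def test_marker_outside_amplicon_dropped(self, tmp_path, caplog):
        path = tmp_path / "mk.tsv"
        path.write_text("chr1\t10001\tv1\tG\tA\t.\n")
        with caplog.at_level("WARNING"):
            markers = load_markers(path, self.AMP)
        assert markers == []
        assert "dropped" in caplog.text

    def test_indel_rejected(self, tmp_path):
        path = tmp_path / "mk.tsv"
        path.write_text("chr1\t151\tv1\tG\tGA\t.\n")
        with pytest.raises(ParseError, match="SNV markers only"):
            load_markers(path, self.AMP)

    def test_round_trip(self, tmp_path):
        m = VariantMarker(
            chrom="chr1", pos=150, ref_base="G", alt_base="A",
            allele_label_ref="x", allele_label_alt="y", hgvs_label="c.1G>A",
        )
        path = tmp_path / "mk.tsv"
        write_markers([m], path)
        assert load_markers(path, self.AMP) == [m]


class TestElements:
    def test_lowercase_uppercased(self, tmp_path):
        path = tmp_path / "e.fa"
        path.write_text(">sva\nacgtacgt\n")
        lib = load_element_library(path)
        assert len(lib) == 1
        assert lib.get("sva").sequence == "ACGTACGT"

    def test_duplicate_names_rejected(self, tmp_path):
        path = tmp_path / "e.fa"
        path.write_text(">sva\nACGT\n>sva\nTTTT\n")
        with pytest.raises(ParseError, match="duplicate"):
            load_element_library(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "e.fa"
        path.write_text("")
        with pytest.raises(ParseError, match="empty"):
            load_element_library(path)


class TestAmplicon:
    def test_wt_length_checked(self):
        with pytest.raises(ConfigError, match="expected_wt_length"):
            Amplicon(model=PLUS, first_exon=1, last_exon=3, expected_wt_length=10)
        ok = Amplicon(
            model=PLUS, first_exon=1, last_exon=3, expected_wt_length=350
        )
        assert ok.genomic_span == (100, 650)

    def test_invalid_range(self):
        with pytest.raises(ConfigError):
            Amplicon(model=PLUS, first_exon=2, last_exon=2)
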