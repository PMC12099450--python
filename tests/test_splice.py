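"""Junction extraction, read classification and quantification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amplisplice.errors import DataError
from amplisplice.models_io import Amplicon, TranscriptModel, VariantMarker
from amplisplice.splice import (
    Elongation,
    ExonSkip,
    InsertionDev,
    IsoformCall,
    Pseudoexon,
    ReadAlignment,
    Truncation,
    build_junction_table,
    classify_read,
    classify_reads,
    extract_junction_chain,
    filter_by_rq,
    isoform_key,
    junction_percentage,
    variant_in_pseudoexon_check,
)

# 6-exon toy model, 100-bp exons, 200-bp introns
EXONS = tuple((300 * i, 300 * i + 100) for i in range(6))
MODEL = TranscriptModel(
    gene_symbol="TOY", transcript_id="TOY.1", chrom="c", strand="+", exons=EXONS
)
AMP = Amplicon(model=MODEL, first_exon=1, last_exon=6)


def read_from_exons(numbers, read_id="r", **kwargs):
    blocks = tuple(MODEL.exon(n) for n in numbers)
    return ReadAlignment(read_id=read_id, blocks=blocks, **kwargs)


class TestJunctionChain:
    def test_canonical_chain_matches_model(self):
        read = read_from_exons(range(1, 7))
        assert extract_junction_chain(read) == MODEL.canonical_junctions()

    def test_skip_removes_two_junctions_adds_bridge(self):
        read = read_from_exons([1, 2, 3, 5, 6])
        chain = extract_junction_chain(read)
        assert (MODEL.exon(3)[1], MODEL.exon(5)[0]) in chain
        assert len(chain) == 4

    def test_single_block_read_has_empty_chain(self):
        read = ReadAlignment(read_id="r", blocks=((0, 100),))
        assert extract_junction_chain(read) == ()


class TestClassify:
    def test_canonical(self):
        call = classify_read(read_from_exons(range(1, 7)), MODEL, AMP)
        assert call.canonical and not call.deviations

    def test_single_skip(self):
        call = classify_read(read_from_exons([1, 2, 3, 5, 6]), MODEL, AMP)
        assert call.deviations == {ExonSkip(exons=(4,))}

    def test_adjacent_skips_merge_into_coskip(self):
        call = classify_read(read_from_exons([1, 2, 5, 6]), MODEL, AMP)
        assert call.deviations == {ExonSkip(exons=(3, 4))}
        assert call.key == "skip[3,4]"

    def test_nonadjacent_skips_stay_separate(self):
        call = classify_read(read_from_exons([1, 3, 5, 6]), MODEL, AMP)
        assert call.deviations == {ExonSkip(exons=(2,)), ExonSkip(exons=(4,))}

    def test_truncation_and_elongation_deltas(self):
        e2 = MODEL.exon(2)
        tail = tuple(MODEL.exon(n) for n in range(3, 7))
        blocks = (MODEL.exon(1), (e2[0], e2[1] - 30)) + tail
        call = classify_read(
            ReadAlignment(read_id="r", blocks=blocks), MODEL, AMP
        )
        assert call.deviations == {Truncation(exon=2, side="end", delta_bp=30)}
        blocks = (MODEL.exon(1), (e2[0], e2[1] + 40)) + tail
        call = classify_read(
            ReadAlignment(read_id="r", blocks=blocks), MODEL, AMP
        )
        assert call.deviations == {Elongation(exon=2, side="end", delta_bp=40)}

    def test_displacement_within_tol_is_canonical(self):
        e2 = MODEL.exon(2)
        blocks = (MODEL.exon(1), (e2[0], e2[1] - 4)) + tuple(
            MODEL.exon(n) for n in range(3, 7)
        )
        call = classify_read(
            ReadAlignment(read_id="r", blocks=blocks), MODEL, AMP, tol=5
        )
        assert call.canonical

    def test_pseudoexon_block_inside_intron(self):
        pe = (MODEL.exon(2)[1] + 50, MODEL.exon(2)[1] + 147)
        blocks = (MODEL.exon(1), MODEL.exon(2), pe) + tuple(
            MODEL.exon(n) for n in range(3, 7)
        )
        call = classify_read(
            ReadAlignment(read_id="r", blocks=blocks), MODEL, AMP
        )
        assert call.deviations == {Pseudoexon(start=pe[0], end=pe[1])}

    def test_elongation_plus_insertion_compose(self):
        e2 = MODEL.exon(2)
        anchor = e2[1] + 39
        blocks = (MODEL.exon(1), (e2[0], anchor)) + tuple(
            MODEL.exon(n) for n in range(3, 7)
        )
        read = ReadAlignment(
            read_id="r", blocks=blocks, insertions=((anchor, "A" * 875),)
        )
        call = classify_read(read, MODEL, AMP)
        assert call.deviations == {
            Elongation(exon=2, side="end", delta_bp=39),
            InsertionDev(anchor=anchor, length=875),
        }

    def test_short_insertion_ignored(self):
        read = ReadAlignment(
            read_id="r",
            blocks=tuple(MODEL.exon(n) for n in range(1, 7)),
            insertions=((150, "ACGT"),),
        )
        call = classify_read(read, MODEL, AMP, min_insertion_len=50)
        assert call.canonical

    def test_read_outside_amplicon_rejected(self):
        read = ReadAlignment(read_id="r", blocks=((5000, 5100),))
        with pytest.raises(DataError, match="amplicon"):
            classify_read(read, MODEL, AMP)

    def test_classification_is_pure(self):
        read = read_from_exons([1, 2, 3, 5, 6])
        first = classify_read(read, MODEL, AMP)
        assert all(
            classify_read(read, MODEL, AMP) == first for _ in range(3)
        )

    @pytest.mark.parametrize("delta", [1, 3, 6, 12, 30])
    def test_raising_tol_never_increases_deviant_calls(self, delta):
        e2 = MODEL.exon(2)
        reads = [
            ReadAlignment(
                read_id=f"r{delta}",
                blocks=(MODEL.exon(1), (e2[0], e2[1] - delta))
                + tuple(MODEL.exon(n) for n in range(3, 7)),
            )
        ]
        deviants = []
        for tol in (0, 2, 5, 10, 40):
            calls = [classify_read(r, MODEL, AMP, tol=tol) for r in reads]
            deviants.append(sum(not c.canonical for c in calls))
        assert deviants == sorted(deviants, reverse=True)


class TestRQFilter:
    def _reads(self, rqs):
        return [
            ReadAlignment(read_id=f"r{i}", blocks=((0, 10),), rq=q)
            for i, q in enumerate(rqs)
        ]

    def test_threshold_is_inclusive(self):
        res = filter_by_rq(self._reads([0.995, 0.99, 0.989]), threshold=0.99)
        assert [r.read_id for r in res.kept] == ["r0", "r1"]
        assert res.n_below == 1

    def test_threshold_zero_keeps_all(self):
        res = filter_by_rq(self._reads([0.1, 0.5, 0.99]), threshold=0.0)
        assert res.n_kept == 3

    def test_missing_rq_retained_and_counted(self, caplog):
        reads = self._reads([0.995]) + [
            ReadAlignment(read_id="untagged", blocks=((0, 10),), rq=None)
        ]
        with caplog.at_level("WARNING"):
            res = filter_by_rq(reads)
        assert res.n_kept == 2 and res.n_missing_rq == 1
        assert "RQ tag" in caplog.text


class TestJunctionPercentage:
    def test_formula(self):
        assert junction_percentage(149, 1000) == 14.9
        assert junction_percentage(0, 1000) == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(DataError, match="total_reads"):
            junction_percentage(0, 0)

    @given(
        total=st.integers(min_value=1, max_value=10**6),
        frac=st.floats(min_value=0, max_value=1),
    )
    @settings(derandomize=True, max_examples=50)
    def test_percentage_bounded(self, total, frac):
        k = min(total, int(frac * total))
        assert 0.0 <= junction_percentage(k, total) <= 100.0


class TestJunctionTable:
    def test_counts_conserved_and_all_canonical(self):
        reads = [read_from_exons(range(1, 7), read_id=f"r{i}") for i in range(5)]
        calls = [classify_read(r, MODEL, AMP) for r in reads]
        table = build_junction_table(calls, reads)
        assert table.isoform_counts == {"canonical": 5}
        assert sum(table.isoform_counts.values()) == table.total_reads
        assert all(c == 5 for c in table.junction_counts.values())

    def test_display_threshold_flags_but_retains(self):
        reads = [read_from_exons(range(1, 7), read_id=f"r{i}") for i in range(3)]
        reads.append(read_from_exons([1, 2, 3, 5, 6], read_id="skip"))
        calls = [classify_read(r, MODEL, AMP) for r in reads]
        table = build_junction_table(calls, reads, display_min_coverage=2)
        bridge = (MODEL.exon(3)[1], MODEL.exon(5)[0])
        assert bridge in table.junction_counts
        assert bridge in table.hidden

    def test_mismatched_ids_error(self):
        reads = [read_from_exons(range(1, 7), read_id="a")]
        calls = [
            IsoformCall(read_id="b", deviations=frozenset(), canonical=True)
        ]
        with pytest.raises(DataError, match="no alignment record"):
            build_junction_table(calls, reads)


class TestPseudoexonVariantCheck:
    PE = (MODEL.exon(2)[1] + 50, MODEL.exon(2)[1] + 147)
    VAR = VariantMarker(
        chrom="c", pos=PE[0] + 40, ref_base="A", alt_base="G",
        allele_label_ref="a1", allele_label_alt="a2",
    )

    def _pe_read(self, read_id, base):
        blocks = (MODEL.exon(1), MODEL.exon(2), self.PE, MODEL.exon(3))
        return ReadAlignment(
            read_id=read_id, blocks=blocks, marker_bases={self.VAR: base}
        )

    def test_alt_fraction(self):
        reads = [self._pe_read(f"r{i}", "G") for i in range(3)]
        reads.append(self._pe_read("ref", "A"))
        reads.append(read_from_exons(range(1, 7), read_id="wt"))
        check = variant_in_pseudoexon_check(reads, self.PE, self.VAR)
        assert check.n_pseudoexon_reads == 4
        assert check.alt_fraction == pytest.approx(0.75)

    def test_empty_set_is_explicit_not_zero(self):
        reads = [read_from_exons(range(1, 7), read_id="wt")]
        check = variant_in_pseudoexon_check(reads, self.PE, self.VAR)
        assert check.n_pseudoexon_reads == 0
        with pytest.raises(DataError, match="no pseudoexon"):
            check.alt_fraction

    def test_variant_outside_interval_rejected(self):
        var = VariantMarker(
            chrom="c", pos=0, ref_base="A", alt_base="G",
            allele_label_ref="a1", allele_label_alt="a2",
        )
        with pytest.raises(DataError, match="inside the pseudoexon"):
            variant_in_pseudoexon_check([], self.PE, var)


class TestIsoformKey:
    def test_identical_sets_identical_keys(self):
        a = {ExonSkip(exons=(16, 17)), Truncation(exon=15, side="end", delta_bp=21)}
        b = {Truncation(exon=15, side="end", delta_bp=21), ExonSkip(exons=(16, 17))}
        assert isoform_key(a) == isoform_key(b)

    def test_coskip_distinct_from_two_singles(self):
        assert isoform_key({ExonSkip(exons=(16, 17))}) != isoform_key(
            {ExonSkip(exons=(16,)), ExonSkip(exons=(17,))}
        )

    def test_empty_is_canonical(self):
        assert isoform_key(set()) == "canonical"
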