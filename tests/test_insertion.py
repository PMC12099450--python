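"""Insertion-event clustering, consensus calling, element identification and
allele decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import gotoh_local_score

from amplisplice.errors import DataError
from amplisplice.insertion import (
    collect_insertion_reads,
    consensus_sequence,
    decompose_insertion,
    identify_element,
    local_alignment_score,
    resolve_genomic_insertion,
    reverse_complement,
    score_donor_sites,
)
from amplisplice.models_io import ElementEntry, ElementLibrary
from amplisplice.splice import ReadAlignment

RNG = np.random.default_rng(2024)


def random_seq(n, rng=RNG):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


ELEMENT = ElementEntry(name="EL", sequence=random_seq(600))
LIBRARY = ElementLibrary(entries=(ELEMENT,))


def ins_read(read_id, anchor, seq):
    return ReadAlignment(
        read_id=read_id, blocks=((0, anchor), (anchor, anchor + 100)),
        insertions=((anchor, seq),),
    )


class TestCollect:
    def test_cluster_requires_min_support(self):
        reads = [ins_read(f"r{i}", 500, "A" * 80) for i in range(9)]
        assert collect_insertion_reads(reads, min_support=10) == []
        reads.append(ins_read("r9", 510, "A" * 80))
        events = collect_insertion_reads(reads, min_support=10)
        assert len(events) == 1
        assert events[0].supporting_reads == 10

    def test_short_insertions_ignored(self):
        reads = [ins_read(f"r{i}", 500, "ACGT") for i in range(20)]
        assert collect_insertion_reads(reads) == []

    def test_distant_payloads_give_two_events(self):
        a = [ins_read(f"a{i}", 500, "A" * 80) for i in range(12)]
        b = [ins_read(f"b{i}", 1000, "C" * 60) for i in range(12)]
        events = collect_insertion_reads(a + b)
        assert len(events) == 2
        assert sorted(e.anchor for e in events) == [500, 1000]

    def test_no_insertions_empty_list(self):
        reads = [ReadAlignment(read_id="r", blocks=((0, 100),))]
        assert collect_insertion_reads(reads) == []


class TestConsensus:
    def test_unanimous(self):
        assert consensus_sequence(["ACGT"] * 5) == "ACGT"

    def test_majority_overrides_minority(self):
        assert consensus_sequence(["ACGT", "ACGT", "ACCT"]) == "ACGT"

    def test_length_is_median(self):
        seqs = ["ACGTACGT", "ACGTACGT", "ACGTAC"]
        assert len(consensus_sequence(seqs)) == 8

    def test_majority_repairs_random_errors(self):
        payload = random_seq(400)
        rng = np.random.default_rng(5)
        seqs = []
        for _ in range(200):
            b = bytearray(payload.encode())
            for p in rng.choice(400, size=rng.binomial(400, 0.002), replace=False):
                b[p] = ord("ACGT"[rng.integers(4)])
            seqs.append(b.decode())
        assert consensus_sequence(seqs) == payload

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            consensus_sequence([])


class TestIdentifyElement:
    def test_exact_substring_full_identity_forward(self):
        hit = identify_element(ELEMENT.sequence[100:300], LIBRARY)
        assert hit.percent_identity == 100.0
        assert hit.orientation == "forward"
        assert hit.element_span == (100, 300)

    def test_reverse_complement_flips_orientation(self):
        fragment = ELEMENT.sequence[100:300]
        fwd = identify_element(fragment, LIBRARY)
        rev = identify_element(reverse_complement(fragment), LIBRARY)
        assert rev.orientation == "reverse"
        assert rev.score == fwd.score
        assert rev.percent_identity == fwd.percent_identity
        assert rev.element_span == fwd.element_span

    def test_unrelated_sequence_no_hit(self):
        rng = np.random.default_rng(99)
        junk = random_seq(30, rng)
        assert identify_element(junk, LIBRARY, min_score=45) is None


class TestSmithWaterman:
    @given(st.data())
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_matches_exhaustive_dp_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        a = random_seq(int(rng.integers(1, 51)), rng)
        b = random_seq(int(rng.integers(1, 51)), rng)
        assert local_alignment_score(a, b) == pytest.approx(
            gotoh_local_score(a, b)
        )

    def test_affine_gap_convention(self):
        # one 1-base gap costs the open score only
        assert local_alignment_score("ACGTACGTAC", "ACGTCGTAC") == 13.0


class TestDecompose:
    def test_pure_forward_fragment_single_segment(self):
        segs = decompose_insertion(ELEMENT.sequence[50:450], LIBRARY)
        assert [s.kind for s in segs] == ["element_fragment"]
        assert segs[0].orientation == "forward"

    def test_literal_inverted_homopolymer_literal(self):
        payload = (
            "G" + reverse_complement(ELEMENT.sequence) + "A" * 38
            + "GACTAGAGAACC"
        )
        segs = decompose_insertion(payload, LIBRARY)
        kinds = [s.kind for s in segs]
        assert kinds == [
            "literal", "element_fragment", "homopolymer", "literal",
        ]
        assert segs[1].orientation == "reverse"
        assert len(segs[2].sequence) == 38
        assert "".join(s.sequence for s in segs) == payload


class TestGenomicResolution:
    def test_error_free_reconstruction_is_byte_exact(self):
        payload = (
            "G" + reverse_complement(ELEMENT.sequence[20:580]) + "A" * 20
            + "TTACGGA"
        )
        reads = [ins_read(f"g{i}", 700, payload) for i in range(14)]
        allele = resolve_genomic_insertion(reads, LIBRARY)
        assert allele.sequence == payload
        assert allele.total_length == len(payload)
        assert allele.insertion_site == (700, 701)
        assert "inv" in allele.description()

    def test_insufficient_support_errors_with_count(self):
        reads = [ins_read(f"g{i}", 700, "A" * 100) for i in range(3)]
        with pytest.raises(DataError, match="3 spanning reads"):
            resolve_genomic_insertion(reads, LIBRARY, min_support=10)


class TestDonorScan:
    def test_planted_canonical_donor_ranks_first(self):
        rng = np.random.default_rng(7)
        seq = list(random_seq(300, rng))
        seq[140:149] = "CAGGTAAGT"
        scores = score_donor_sites("".join(seq), top_k=3)
        assert scores[0].position == 143
        assert scores[0].passes_gt_rule

    def test_all_a_sequence_empty_under_gt_rule(self):
        assert score_donor_sites("A" * 100) == []

    def test_gt_filter_disabled_reports_non_gt(self):
        scores = score_donor_sites("A" * 100, gt_filter=False, top_k=2)
        assert scores and not scores[0].passes_gt_rule

    def test_too_short_consensus_rejected(self):
        with pytest.raises(DataError, match="PWM width"):
            score_donor_sites("ACGT")
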