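"""Pseudo-circularization and coordinate folding."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitolong import circref
from mitolong.circref import (
    LinearAlignment,
    fold_alignment,
    fold_read_alignments,
    group_by_read,
    parse_cigar,
    parse_paf,
    pseudo_circularize,
    segment_coverage,
    wrap_overlap,
    write_paf,
)

from conftest import brute_force_fold


class TestPseudoCircularize:
    @pytest.mark.parametrize("seq,doubled,L", [
        ("ACGT", "ACGTACGT", 4),
        ("A", "AA", 1),
    ])
    def test_doubling(self, seq, doubled, L):
        ref = pseudo_circularize(seq)
        assert ref.doubled_sequence == doubled
        assert ref.length == L

    def test_study_scale_doubling(self):
        ref = pseudo_circularize("A" * 16666)
        assert len(ref.doubled_sequence) == 33332

    def test_errors(self):
        with pytest.raises(ValueError, match="empty reference"):
            pseudo_circularize("")
        with pytest.raises(ValueError, match="invalid alphabet"):
            pseudo_circularize("ACGU")

    def test_doubling_idempotent_on_length(self):
        ref = pseudo_circularize("ACGTNACGT")
        assert ref.doubled_sequence[:ref.length] == ref.sequence


class TestFoldAlignment:
    def test_no_origin_crossing(self, circle16k):
        aln = LinearAlignment("r", 100, 100, 200, "+", 100)
        folded = fold_alignment(aln, circle16k)
        assert folded.segments == [(100, 200, "+")]
        assert folded.distinct_ref_span == 100

    def test_origin_crossing_splits(self, circle16k):
        aln = LinearAlignment("r", 10, 16660, 16670, "+", 10)
        folded = fold_alignment(aln, circle16k)
        assert folded.segments == [(16660, 16666, "+"), (0, 4, "+")]
        assert folded.distinct_ref_span == 10

    def test_full_double_circle(self):
        ref = pseudo_circularize("A" * 100)
        aln = LinearAlignment("r", 200, 0, 200, "+", 200)
        folded = fold_alignment(aln, ref)
        assert folded.ref_span == 200
        assert folded.distinct_ref_span == 100

    def test_start_beyond_L_normalized(self, circle16k):
        lo = fold_alignment(LinearAlignment("r", 50, 100, 150, "+", 50), circle16k)
        hi = fold_alignment(LinearAlignment("r", 50, 16766, 16816, "+", 50), circle16k)
        assert lo.segments == hi.segments

    def test_out_of_range_interval(self, circle16k):
        with pytest.raises(ValueError, match="coordinate out of doubled reference"):
            fold_alignment(LinearAlignment("r", 10, 33330, 33340, "+", 10), circle16k)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_fold_matches_per_base_oracle(self, data):
        L = data.draw(st.integers(min_value=2, max_value=300))
        start = data.draw(st.integers(min_value=0, max_value=2 * L - 2))
        end = data.draw(st.integers(min_value=start + 1, max_value=2 * L))
        ref = pseudo_circularize("A" * L)
        aln = LinearAlignment("r", end - start, start, end, "+", end - start)
        folded = fold_alignment(aln, ref)
        oracle = collections.Counter(brute_force_fold(start, end, L))
        got = collections.Counter()
        for s, e, _ in folded.segments:
            got.update(range(s, e))
        # folding normalizes start mod L; the oracle is shift-invariant mod L
        assert got == oracle
        assert folded.distinct_ref_span == len(oracle)
        assert folded.ref_span == end - start
        # distinct + double-covered == ref_span when span <= L, else caps at L
        assert folded.distinct_ref_span == min(folded.ref_span, L)


class TestWrapOverlap:
    @pytest.mark.parametrize("span,expected", [
        (17501, 835),   # the archetypal multi-revolution read
        (16666, 0),     # exactly one revolution
        (8000, 0),      # sub-revolution
    ])
    def test_contiguous_interval(self, circle16k, span, expected):
        aln = LinearAlignment("r", span, 0, span, "+", span)
        folded = fold_alignment(aln, circle16k)
        assert wrap_overlap(folded, circle16k) == expected
        # agreement with the per-base multiplicity oracle
        counts = collections.Counter(brute_force_fold(0, span, circle16k.length))
        assert wrap_overlap(folded, circle16k) == sum(1 for v in counts.values() if v >= 2)


class TestGroupedFolding:
    def test_union_fraction_from_query_intervals(self, circle16k):
        alns = [
            LinearAlignment("r", 1000, 0, 500, "+", 500, query_start=0, query_end=500),
            LinearAlignment("r", 1000, 600, 1000, "+", 400, query_start=400, query_end=800),
        ]
        folded = fold_read_alignments(alns, circle16k)
        assert folded.aligned_read_fraction == pytest.approx(0.8)
        assert folded.ref_span == 900

    def test_mixed_reads_rejected(self, circle16k):
        alns = [
            LinearAlignment("a", 100, 0, 100, "+", 100),
            LinearAlignment("b", 100, 0, 100, "+", 100),
        ]
        with pytest.raises(ValueError, match="different reads"):
            fold_read_alignments(alns, circle16k)


class TestSegmentCoverage:
    def test_invalid_segment(self):
        with pytest.raises(ValueError, match="outside circle"):
            segment_coverage([(5, 3, "+")], 10)

    def test_multiplicity(self):
        cov = segment_coverage([(0, 6, "+"), (4, 10, "+")], 10)
        assert list(cov) == [1, 1, 1, 1, 2, 2, 1, 1, 1, 1]


class TestPafRoundTrip:
    def test_round_trip(self, tmp_path, circle16k):
        alns = [
            LinearAlignment("readA", 5000, 100, 5100, "+", 5000,
                            query_start=0, query_end=5000,
                            cigar=parse_cigar("2500M10D2500M"), mapq=60),
            LinearAlignment("readB", 3000, 200, 3100, "-", 2900,
                            query_start=50, query_end=2950, mapq=42),
        ]
        path = tmp_path / "test.paf"
        write_paf(alns, circle16k.doubled_id, 2 * circle16k.length, path)
        back = parse_paf(path)
        assert len(back) == 2
        assert back[0].cigar == alns[0].cigar
        assert (back[1].ref_start, back[1].ref_end, back[1].strand) == (200, 3100, "-")
        groups = group_by_read(back)
        assert set(groups) == {"readA", "readB"}

    def test_sam_parsing_matches_paf(self, tmp_path, circle16k):
        sam = tmp_path / "t.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            f"@SQ\tSN:{circle16k.doubled_id}\tLN:{2 * circle16k.length}\n"
            f"r1\t0\t{circle16k.doubled_id}\t101\t60\t50M\t*\t0\t0\t{'A' * 50}\t{'I' * 50}\n"
        )
        alns = circref.parse_sam(sam)
        assert len(alns) == 1
        assert (alns[0].ref_start, alns[0].ref_end) == (100, 150)
        assert alns[0].cigar == [("M", 50)]
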