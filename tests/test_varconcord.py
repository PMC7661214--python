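"""Pileup SNP calling and strict multi-library concordance."""

import math

import numpy as np
import pytest
from scipy import stats

from mitolong import simkit
from mitolong.circref import LinearAlignment
from mitolong.readqc import ReadRecord, filter_reads
from mitolong.varconcord import (
    ConcordanceCounts,
    VariantCall,
    f1_score,
    found_in_all_fraction,
    pileup_call,
    presence_matrix,
    read_vcf,
    strict_concordance,
    strict_counts,
    ts_tv_ratio,
    write_vcf,
)


class TestF1Score:
    @pytest.mark.parametrize("p,r,expected", [
        (1.000, 0.931, 0.964),
        (0.982, 0.915, 0.947),
        (0.980, 0.926, 0.952),
        (0.980, 0.909, 0.943),
        (0.857, 0.750, 0.800),
        (1.000, 0.925, 0.961),
        (1.000, 0.957, 0.978),
        (0.5, 0.5, 0.5),
        (1.0, 1.0, 1.0),
    ])
    def test_harmonic_mean_rounded(self, p, r, expected):
        assert f1_score(p, r) == expected

    def test_degenerate_zero(self):
        with pytest.warns(UserWarning):
            assert f1_score(0.0, 0.0) == 0.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            f1_score(1.2, 0.5)

    def test_grid_against_brute_force(self):
        # harmonic mean and betweenness on a 100x100 grid
        grid = np.linspace(0.01, 1.0, 100)
        for p in grid:
            for r in grid:
                expected = round(2 * p * r / (p + r) + 1e-12, 3)
                got = f1_score(float(p), float(r))
                assert abs(got - 2 * p * r / (p + r)) <= 0.0005 + 1e-9
                assert min(p, r) - 0.0005 <= got <= max(p, r) + 0.0005


class TestFoundInAll:
    @pytest.mark.parametrize("k,n,expected", [
        (73, 77, 94.8),
        (77, 83, 92.8),
        (72, 74, 97.3),
        (7, 9, 77.8),
        (82, 85, 96.5),
        (9, 9, 100.0),
    ])
    def test_printed_percentages(self, k, n, expected):
        presence = np.ones((n, 7), dtype=bool)
        presence[k:, 0] = False  # k variants found in all 7 libraries
        got_k, got_n, pct = found_in_all_fraction(presence)
        assert (got_k, got_n) == (k, n)
        assert pct == expected

    def test_empty_matrix(self):
        with pytest.raises(ValueError):
            found_in_all_fraction(np.zeros((0, 7), dtype=bool))


class TestStrictRule:
    def test_called_everywhere_is_tp(self):
        truth = [(100, "A", "G")]
        calls = {f"lib{i}": [(100, "A", "G")] for i in range(7)}
        counts = strict_counts(calls, truth)
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)
        assert counts.precision == counts.recall == 1.0
        assert counts.f1 == 1.0

    def test_missed_in_one_library_is_fn(self):
        truth = [(100, "A", "G")]
        calls = {f"lib{i}": [(100, "A", "G")] for i in range(6)}
        calls["lib6"] = []
        counts = strict_counts(calls, truth)
        assert (counts.tp, counts.fn) == (0, 1)

    def test_call_outside_truth_is_fp(self):
        counts = strict_counts({"lib0": [(5, "C", "T")], "lib1": []}, [])
        assert counts.fp == 1

    def test_single_library_reduces_to_plain_concordance(self):
        truth = [(1, "A", "G"), (2, "C", "T"), (3, "G", "A")]
        called = [(1, "A", "G"), (3, "G", "A"), (9, "C", "T")]
        counts = strict_counts({"only": called}, truth)
        assert (counts.tp, counts.fp, counts.fn) == (2, 1, 1)

    def test_region_restriction(self):
        truth = [(100, "A", "G"), (5000, "C", "T")]
        calls = {"lib0": [(100, "A", "G")]}
        counts = strict_counts(calls, truth, regions=[(1, 1000)])
        assert (counts.tp, counts.fn) == (1, 0)

    def test_pooled_all_row(self):
        calls = {
            "h1": {"a": [(1, "A", "G")], "b": [(1, "A", "G")]},
            "h2": {"a": [], "b": []},
        }
        truth = {"h1": [(1, "A", "G")], "h2": [(2, "C", "T")]}
        results = strict_concordance(calls, truth)
        assert results["All"].tp == 1 and results["All"].fn == 1

    def test_undefined_precision_warns(self):
        counts = ConcordanceCounts(tp=0, fp=0, fn=3)
        with pytest.warns(UserWarning, match="precision undefined"):
            assert math.isnan(counts.precision)


class TestPileupCall:
    @staticmethod
    def _make_site(ref, depth, alt_count, pos=50):
        """Reads of length 1 covering one position, alt_count of them alt."""
        ref_base = ref.sequence[pos]
        alt_base = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
        reads, alns = {}, []
        for i in range(depth):
            base = alt_base if i < alt_count else ref_base
            rid = f"r{i}"
            reads[rid] = ReadRecord(rid, base, [30])
            alns.append(LinearAlignment(rid, 1, pos, pos + 1, "+", 1,
                                        query_start=0, query_end=1,
                                        cigar=[("M", 1)]))
        return reads, alns, (pos + 1, ref_base, alt_base)

    def test_planted_snp_called(self, circle16k):
        reads, alns, key = self._make_site(circle16k, depth=100, alt_count=90)
        calls = pileup_call(alns, reads, circle16k, error_rate=0.1)
        assert [c.key for c in calls] == [key]
        (call,) = calls
        # binomial-tail oracle at p=0.1, k>=90 of 100
        expected_q = -10 * stats.binom.logsf(89, 100, 0.1) / math.log(10)
        assert call.quality == pytest.approx(expected_q)
        assert call.quality > 15

    def test_error_level_alt_not_called(self, circle16k):
        reads, alns, _ = self._make_site(circle16k, depth=100, alt_count=10)
        assert pileup_call(alns, reads, circle16k, error_rate=0.1) == []

    def test_zero_depth_no_call(self, circle16k):
        assert pileup_call([], {}, circle16k) == []

    def test_minus_strand_pileup(self, circle16k):
        # a '-' strand alignment must be complemented before counting
        from mitolong._util import revcomp

        pos = 10
        segment = circle16k.sequence[pos:pos + 20]
        rid = "rev"
        reads = {rid: ReadRecord(rid, revcomp(segment), [30] * 20)}
        alns = [LinearAlignment(rid, 20, pos, pos + 20, "-", 20,
                                query_start=0, query_end=20, cigar=[("M", 20)])]
        # perfectly matching reference in reverse orientation: no calls
        assert pileup_call(alns, reads, circle16k, error_rate=0.1) == []

    def test_wrapped_alignment_folds_onto_circle(self, circle16k):
        # a read on the second copy of the doubled reference piles onto [0, L)
        L = circle16k.length
        pos = 5
        segment = circle16k.sequence[pos:pos + 10]
        alt_seg = ("G" if segment[0] != "G" else "A") + segment[1:]
        rid = "wrap"
        reads = {rid: ReadRecord(rid, alt_seg * 12, [30] * 120)}
        alns = [LinearAlignment(rid, 120, L + pos, L + pos + 10, "+", 10,
                                query_start=0, query_end=10, cigar=[("M", 10)])
                for _ in range(60)]
        calls = pileup_call(alns, reads, circle16k, error_rate=0.1)
        assert len(calls) == 1
        assert calls[0].position == pos + 1


class TestTsTv:
    def test_all_transitions_is_infinite(self):
        calls = [VariantCall(1, "A", "G", 30.0), VariantCall(2, "C", "T", 30.0)]
        assert ts_tv_ratio(calls) == float("inf")

    def test_mixed(self):
        calls = [VariantCall(1, "A", "G", 30.0), VariantCall(2, "C", "G", 30.0)]
        assert ts_tv_ratio(calls) == 1.0


class TestSimulatedConcordance:
    def test_strict_rule_on_simulated_libraries(self):
        """Planted homoplasmic SNPs recovered across 3 simulated libraries."""
        config = simkit.SimulationConfig(seed=21, n_reads=900, mt_read_fraction=1.0,
                                         chimera_2d_rate=0.0, n_haplotype_snps=20)
        genomes = simkit.generate_genomes(config)
        calls_by_lib = {}
        for lib in range(3):
            sim = simkit.simulate_reads(config, genomes, library=lib)
            kept, _ = filter_reads(sim.reads)
            reads_by_id = {r.id: r for r in kept}
            alns = [a for a in sim.truth_alignments if a.read_id in reads_by_id]
            calls = pileup_call(alns, reads_by_id, genomes.reference, error_rate=0.1)
            calls_by_lib[f"lib{lib}"] = [c.key for c in calls]
        truth = [v.key for v in genomes.truth_variants]
        counts = strict_counts(calls_by_lib, truth)
        assert counts.precision >= 0.99
        assert counts.recall >= 0.9


class TestVcfRoundTrip:
    def test_round_trip_and_filter(self, tmp_path, circle16k):
        calls = [
            VariantCall(100, "A", "G", 42.0),
            VariantCall(200, "C", "T", 7.0),  # below cutoff -> FILTER q15
        ]
        path = tmp_path / "calls.vcf"
        write_vcf(calls, circle16k, path)
        text = path.read_text()
        assert "q15" in text
        back = read_vcf(path, horse="h1", library="l1")
        assert [c.key for c in back] == [(100, "A", "G"), (200, "C", "T")]
        assert back[0].quality == pytest.approx(42.0)


def test_presence_matrix_with_qualities():
    calls = {"l1": [(1, "A", "G"), (2, "C", "T")], "l2": [(1, "A", "G")]}
    quals = {"l1": {(1, "A", "G"): 30.0, (2, "C", "T"): 18.0},
             "l2": {(1, "A", "G"): 25.0}}
    df = presence_matrix(calls, quals)
    assert df.loc["1:A>G", "pooled"] == 30.0  # pooled per-variant quality = max
    assert np.isnan(df.loc["2:C>T", "l2"])
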