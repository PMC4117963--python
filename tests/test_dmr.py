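"""DMR calling: merging, read counting, the 2x2 chi-square against a
textbook oracle, BH against the step-up definition, boundary rules and
symmetry/monotonicity properties."""

import numpy as np
import pytest
from scipy import stats

from medipmap.dmr import (
    MergedRegion,
    bh_adjust,
    call_dmrs,
    count_reads,
    merge_peak_sets,
    significant,
)
from medipmap.dmr import test_region as region_test
from medipmap.dmr import test_regions as regions_test
from medipmap.intervals import GenomicInterval
from medipmap.simulate import simulate_region_counts

from oracles import bh_stepup, bp_mask, chi2_2x2, mask_to_spans


def _iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


class TestMergePeakSets:
    def test_overlapping_peaks_union(self):
        merged = merge_peak_sets([_iv(100, 200)], [_iv(150, 300)])
        assert [(m.start, m.end) for m in merged] == [(100, 300)]

    def test_disjoint_sets_concatenate(self):
        a = [_iv(0, 50), _iv(1000, 1100)]
        b = [_iv(200, 300)]
        merged = merge_peak_sets(a, b)
        assert len(merged) == 3
        assert [m.start for m in merged] == [0, 200, 1000]

    def test_matches_bp_union_oracle(self, rng):
        a = [_iv(int(s), int(s) + int(rng.integers(50, 400))) for s in rng.integers(0, 50_000, 40)]
        b = [_iv(int(s), int(s) + int(rng.integers(50, 400))) for s in rng.integers(0, 50_000, 40)]
        merged = merge_peak_sets(a, b)
        mask = bp_mask(60_000, [(p.start, p.end) for p in a + b])
        assert [(m.start, m.end) for m in merged] == mask_to_spans(mask)


class TestCountReads:
    def test_contained_read_counted(self):
        assert count_reads([_iv(100, 400)], [_iv(200, 250)])[0] == 1

    def test_forty_percent_overlap_not_counted(self):
        # 20 of 50 bp inside (40%) < 50% default
        assert count_reads([_iv(100, 400)], [_iv(380, 430)])[0] == 0

    def test_read_assigned_once_to_max_overlap_region(self):
        regions = [_iv(0, 100), _iv(100, 300)]
        counts = count_reads(regions, [_iv(80, 130)])  # 20 bp vs 30 bp
        assert counts.tolist() == [0, 1]

    def test_matches_brute_force_overlap_oracle(self, rng):
        regions = merge_peak_sets(
            [_iv(int(s), int(s) + int(rng.integers(100, 500))) for s in rng.integers(0, 80_000, 50)], []
        )
        reads = [_iv(int(s), int(s) + 50) for s in rng.integers(0, 80_000, 800)]
        counts = count_reads(regions, reads)
        oracle = np.zeros(len(regions), dtype=int)
        for r in reads:
            ovs = [max(0, min(g.end, r.end) - max(g.start, r.start)) for g in regions]
            j = int(np.argmax(ovs))
            if ovs[j] >= 0.5 * r.length:
                oracle[j] += 1
        assert counts.tolist() == oracle.tolist()


class TestChiSquare:
    def test_symmetric_table_is_null(self):
        rec = region_test(MergedRegion(_iv(0, 100), 30, 30, 1000, 1000))
        assert rec.chi2 == pytest.approx(0.0)
        assert rec.p == pytest.approx(1.0)
        assert rec.fold == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "a,b,na,nb", [(30, 10, 1000, 1000), (5, 40, 2000, 1500), (100, 80, 10_000, 12_000)]
    )
    def test_statistic_matches_textbook_oracle(self, a, b, na, nb):
        rec = region_test(MergedRegion(_iv(0, 100), a, b, na, nb))
        assert rec.chi2 == pytest.approx(chi2_2x2(a, b, na, nb), rel=1e-12)
        assert rec.p == pytest.approx(stats.chi2.sf(chi2_2x2(a, b, na, nb), 1))

    def test_thirty_vs_ten_equal_totals(self):
        rec = region_test(MergedRegion(_iv(0, 100), 30, 10, 1000, 1000))
        assert rec.fold == pytest.approx(3.0)
        assert rec.chi2 == pytest.approx(chi2_2x2(30, 10, 1000, 1000))

    def test_exact_twofold_excluded_by_strict_rule(self):
        regions = [MergedRegion(_iv(0, 100), 20, 10, 1000, 1000)] + [
            MergedRegion(_iv(i * 1000, i * 1000 + 100), 400, 10, 1000, 1000) for i in range(1, 4)
        ]
        recs = regions_test(regions)
        assert recs[0].fold == pytest.approx(2.0)
        assert not recs[0].is_dmr  # "greater than 2-fold" is strict

    def test_zero_information_region_rejected(self):
        with pytest.raises(ValueError, match="uninformative"):
            region_test(MergedRegion(_iv(0, 100), 0, 0, 1000, 1000))

    def test_pseudocount_applies_to_zero_cells_for_fold_only(self):
        rec = region_test(MergedRegion(_iv(0, 100), 20, 0, 1000, 1000))
        assert rec.fold == pytest.approx(40.0)  # 20 / 0.5
        assert rec.chi2 == pytest.approx(chi2_2x2(20, 0, 1000, 1000))


class TestBH:
    @pytest.mark.parametrize("n", [1, 2, 5, 20])
    def test_matches_stepup_definition_oracle(self, n, rng):
        p = rng.random(n)
        assert bh_adjust(p) == pytest.approx(bh_stepup(p), rel=1e-12)

    def test_single_pvalue_q_equals_p(self):
        assert bh_adjust([0.031])[0] == pytest.approx(0.031)

    def test_q_never_below_p(self, rng):
        p = rng.random(50)
        assert np.all(bh_adjust(p) >= p - 1e-15)


class TestCallDmrs:
    def test_identical_inputs_give_zero_dmrs(self, small_study):
        peaks = small_study["peaks"]["sampleA"]
        reads = small_study["reads"]["sampleA"]
        records = call_dmrs(peaks, peaks, reads, reads)
        assert significant(records) == []
        assert all(r.chi2 == pytest.approx(0.0) for r in records)

    def test_swapping_samples_flips_direction_and_inverts_fold(self):
        regions, _ = simulate_region_counts(50, 10, fold=4.0, mean=10.0, seed=2)
        fwd = regions_test(regions)
        swapped = [
            MergedRegion(r.interval, r.count_b, r.count_a, r.total_b, r.total_a)
            for r in regions
        ]
        rev = regions_test(swapped)
        for f, r in zip(fwd, rev):
            assert f.chi2 == pytest.approx(r.chi2)
            assert f.p == pytest.approx(r.p)
            assert f.q == pytest.approx(r.q)
            assert f.fold == pytest.approx(1.0 / r.fold)
            assert f.is_dmr == r.is_dmr
            if f.is_dmr:
                assert {f.direction, r.direction} == {"hyper", "hypo"}

    def test_min_fold_monotonicity(self):
        regions, _ = simulate_region_counts(300, 30, fold=3.0, mean=15.0, seed=3)
        n_prev = None
        for mf in (1.5, 2.0, 3.0, 4.0):
            n = len(significant(regions_test(regions, min_fold=mf)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError, match="zero total reads"):
            call_dmrs([_iv(0, 100)], [_iv(0, 100)], [], [_iv(0, 50)])

    def test_planted_dmrs_recovered_in_full_pipeline(self, small_study):
        """End-to-end: planted fold-4 DMRs in the simulated study are
        recovered from peaks + reads."""
        peaks = small_study["peaks"]
        reads = small_study["reads"]
        truth = small_study["truth_methylome"]
        records = call_dmrs(
            peaks["sampleA"], peaks["sampleB"], reads["sampleA"], reads["sampleB"]
        )
        sig = significant(records)
        called = {(r.interval.chrom, r.interval.start, r.interval.end) for r in sig}
        hits = 0
        for d in truth.dmrs:
            if any(
                c == d["chrom"] and s <= d["start"] and e >= d["end"]
                for c, s, e in called
            ):
                hits += 1
        assert hits / len(truth.dmrs) >= 0.9
        # directions match truth for the recovered ones
        by_span = {
            (r.interval.chrom, r.interval.start, r.interval.end): r.direction for r in sig
        }
        agree = sum(
            1
            for d in truth.dmrs
            if by_span.get((d["chrom"], d["start"], d["end"])) == d["direction"]
        )
        assert agree >= 0.8 * hits
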