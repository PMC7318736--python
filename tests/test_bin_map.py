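"""Sliding-window genotyping, bin construction, and the merge/filter rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from csslkit.bin_map import (
    CALL_DONOR,
    CALL_HET,
    CALL_MISSING,
    CALL_RECIPIENT,
    Bin,
    BinCallingParams,
    SnpTable,
    bins_to_segments,
    call_windows,
    filter_alleles,
    infer_segments,
    merge_and_filter,
    windows_to_bins,
)
from csslkit.genome import DONOR_HOM, HET, NA, RECIPIENT_HOM
from csslkit.synthetic import SimConfig, simulate_population

P = BinCallingParams()


class TestFilterAlleles:
    def test_parental_calls_classified(self):
        geno = np.array([["A/A", "T/T", "A/T", "./."]], dtype=object)
        rec = np.array(["A", "A", "A", "A"], dtype=object)
        don = np.array(["T", "T", "T", "T"], dtype=object)
        keep, calls = filter_alleles(geno, rec, don)
        assert keep.all()
        assert list(calls[0]) == [CALL_RECIPIENT, CALL_DONOR, CALL_HET, CALL_MISSING]

    def test_third_allele_set_missing(self):
        geno = np.array([["G/G"], ["A/G"]], dtype=object)
        keep, calls = filter_alleles(geno, np.array(["A"], dtype=object), np.array(["T"], dtype=object))
        assert calls[0, 0] == CALL_MISSING  # both alleles foreign
        assert calls[1, 0] == CALL_MISSING  # one allele foreign

    def test_monomorphic_sites_dropped(self):
        geno = np.array([["A/A", "T/T"]], dtype=object)
        rec = np.array(["A", "A"], dtype=object)
        don = np.array(["A", "T"], dtype=object)
        keep, calls = filter_alleles(geno, rec, don)
        assert list(keep) == [False, True]
        assert calls.shape == (1, 1)

    def test_identical_parents_abort(self):
        geno = np.array([["A/A"]], dtype=object)
        same = np.array(["A"], dtype=object)
        with pytest.raises(ValueError, match="identical"):
            filter_alleles(geno, same, same)


class TestCallWindows:
    def _window(self, calls_list, chrom_length=50_000):
        """One window's worth of SNPs spread over a single window."""
        pos = np.linspace(0, chrom_length - 1, len(calls_list)).astype(np.int64)
        calls = np.array([calls_list], dtype=np.int8)
        params = BinCallingParams(window_size=chrom_length, step=chrom_length)
        return call_windows(pos, calls, chrom_length, params)[0, 0]

    def test_majority_donor(self):
        assert self._window([CALL_DONOR] * 9 + [CALL_RECIPIENT]) == CALL_DONOR  # 0.9 > 0.8

    def test_exact_threshold_not_exceeded_is_het(self):
        assert self._window([CALL_DONOR] * 8 + [CALL_RECIPIENT] * 2) == CALL_HET  # 0.8 not > 0.8

    def test_balanced_window_is_het(self):
        assert self._window([CALL_DONOR] * 5 + [CALL_RECIPIENT] * 5) == CALL_HET

    def test_het_dominated_window_is_het(self):
        assert self._window([CALL_HET] * 9 + [CALL_DONOR]) == CALL_HET

    def test_too_few_informative_snps_is_na(self):
        assert self._window([CALL_DONOR] * 3 + [CALL_MISSING] * 7) == CALL_MISSING

    def test_empty_chromosome(self):
        out = call_windows(np.array([], dtype=np.int64), np.empty((1, 0), np.int8), 0, P)
        assert out.shape[1] == 0


class TestWindowsToBins:
    def test_breakpoint_at_midpoint_of_transition_overlap(self):
        """10 donor then 10 recipient windows (50 kb / 5 kb): the boundary
        falls midway between the centers of windows 10 and 11, at 72.5 kb."""
        w = np.array([CALL_DONOR] * 10 + [CALL_RECIPIENT] * 10, dtype=np.int8)
        params = BinCallingParams(window_size=50_000, step=5_000)
        bins = windows_to_bins(w, 100_000, params, line="L1", chrom="c")
        assert len(bins) == 2
        assert bins[0].end == 72_500
        assert (bins[0].genotype, bins[1].genotype) == (DONOR_HOM, RECIPIENT_HOM)
        assert bins[0].start == 0 and bins[1].end == 100_000

    def test_uniform_windows_give_single_bin(self):
        w = np.full(40, CALL_DONOR, dtype=np.int8)
        bins = windows_to_bins(w, 200_000, P, line="L1", chrom="c")
        assert len(bins) == 1
        assert (bins[0].start, bins[0].end) == (0, 200_000)

    def test_alternating_windows_make_unit_runs(self):
        w = np.array([CALL_DONOR, CALL_RECIPIENT] * 10, dtype=np.int8)
        bins = windows_to_bins(w, 100_000, P, line="L1", chrom="c")
        assert len(bins) == 20
        assert all(b.length < P.min_bin for b in bins)

    def test_bins_tile_chromosome(self):
        w = np.array([CALL_DONOR] * 7 + [CALL_MISSING] * 5 + [CALL_HET] * 8, dtype=np.int8)
        bins = windows_to_bins(w, 100_000, P, line="L1", chrom="c")
        assert bins[0].start == 0 and bins[-1].end == 100_000
        assert all(a.end == b.start for a, b in zip(bins, bins[1:]))


def _bin(start, end, genotype, line="L1", chrom="c"):
    return Bin(line=line, chrom=chrom, start=start, end=end, genotype=genotype)


class TestMergeAndFilter:
    def test_same_genotype_bins_fused_across_short_gap(self):
        bins = [
            _bin(0, 500_000, DONOR_HOM),
            _bin(500_000, 580_000, RECIPIENT_HOM),  # 80 kb < 100 kb
            _bin(580_000, 1_000_000, DONOR_HOM),
        ]
        out = merge_and_filter(bins, P)
        assert [(b.start, b.end, b.genotype) for b in out] == [(0, 1_000_000, DONOR_HOM)]

    def test_large_gap_not_fused(self):
        bins = [
            _bin(0, 500_000, DONOR_HOM),
            _bin(500_000, 650_000, RECIPIENT_HOM),  # 150 kb >= 100 kb
            _bin(650_000, 1_000_000, DONOR_HOM),
        ]
        out = merge_and_filter(bins, P)
        assert len(out) == 3

    def test_short_isolated_bin_removed(self):
        bins = [
            _bin(0, 500_000, RECIPIENT_HOM),
            _bin(500_000, 595_000, DONOR_HOM),  # 95 kb < 100 kb
            _bin(595_000, 1_200_000, RECIPIENT_HOM),
        ]
        out = merge_and_filter(bins, P)
        assert all(b.genotype != DONOR_HOM for b in out)
        # absorbed into the surrounding recipient background
        assert [(b.start, b.end, b.genotype) for b in out] == [(0, 1_200_000, RECIPIENT_HOM)]

    def test_idempotent(self):
        bins = [
            _bin(0, 95_000, DONOR_HOM),
            _bin(95_000, 160_000, NA),
            _bin(160_000, 600_000, DONOR_HOM),
            _bin(600_000, 640_000, HET),
            _bin(640_000, 1_000_000, RECIPIENT_HOM),
        ]
        once = merge_and_filter(bins, P)
        twice = merge_and_filter(once, P)
        assert [(b.start, b.end, b.genotype) for b in once] == [
            (b.start, b.end, b.genotype) for b in twice
        ]

    @given(st.lists(st.sampled_from([DONOR_HOM, RECIPIENT_HOM, HET, NA]), min_size=1, max_size=12),
           st.lists(st.integers(10_000, 400_000), min_size=1, max_size=12))
    def test_idempotent_and_tiling_on_random_layouts(self, genotypes, lengths):
        k = min(len(genotypes), len(lengths))
        start, bins = 0, []
        for g, ln in zip(genotypes[:k], lengths[:k]):
            bins.append(_bin(start, start + ln, g))
            start += ln
        once = merge_and_filter(bins, P)
        twice = merge_and_filter(once, P)
        assert [(b.start, b.end, b.genotype) for b in once] == [
            (b.start, b.end, b.genotype) for b in twice
        ]
        assert once[0].start == 0 and once[-1].end == start
        assert all(a.end == b.start for a, b in zip(once, once[1:]))


class TestSegments:
    def test_background_line_has_no_segments(self):
        bins = [_bin(0, 1_000_000, RECIPIENT_HOM), _bin(1_000_000, 1_200_000, NA)]
        assert bins_to_segments(bins) == []

    def test_donor_bin_becomes_segment(self):
        (seg,) = bins_to_segments([_bin(1_000_000, 3_500_000, DONOR_HOM)])
        assert seg.length == 2_500_000
        assert seg.state == DONOR_HOM

    def test_adjacent_donor_and_het_bins_stay_distinct(self):
        segs = bins_to_segments(
            [_bin(0, 500_000, DONOR_HOM), _bin(500_000, 900_000, HET)]
        )
        assert [s.state for s in segs] == [DONOR_HOM, HET]


class TestPipeline:
    def test_bins_tile_each_chromosome(self, two_chrom_config, recovered_segments):
        bins, _ = recovered_segments
        for chrom, length in two_chrom_config.chromosome_lengths.items():
            for line in {b.line for b in bins}:
                lb = sorted(
                    (b for b in bins if b.chrom == chrom and b.line == line),
                    key=lambda b: b.start,
                )
                assert lb[0].start == 0 and lb[-1].end == length
                assert sum(b.length for b in lb) == length

    def test_recovery_of_planted_segments(self, two_chrom_config, small_population, recovered_segments):
        from conftest import match_segments

        _, _, truth = small_population
        _, segments = recovered_segments
        matches, misses, spurious = match_segments(truth.segments, segments)
        assert not misses
        for ts, rs in matches:
            assert abs(rs.start - ts.start) <= 50_000
            assert abs(rs.end - ts.end) <= 50_000
        assert not [s for s in spurious if s.length >= 200_000]

    def test_invariant_to_snp_input_order(self, two_chrom_config, small_population):
        snp_table, _, _ = small_population
        rng = np.random.default_rng(0)
        shuffled_pos, shuffled_calls = {}, {}
        for chrom in snp_table.chroms:
            order = rng.permutation(len(snp_table.positions[chrom]))
            shuffled_pos[chrom] = snp_table.positions[chrom][order]
            shuffled_calls[chrom] = snp_table.calls[chrom][:, order]
        shuffled = SnpTable(
            lines=snp_table.lines, chroms=snp_table.chroms,
            positions=shuffled_pos, calls=shuffled_calls,
        )
        _, seg_a = infer_segments(snp_table, two_chrom_config.genome)
        _, seg_b = infer_segments(shuffled, two_chrom_config.genome)
        assert sorted(seg_a) == sorted(seg_b)

    def test_lines_without_introgressions_yield_no_segments(self):
        cfg = SimConfig(
            chromosome_lengths={"A01": 5_000_000}, n_lines=2, segments_per_line=(1, 1),
            segment_length=(1_000_000, 2_000_000), genotyping_error=0.0, missing_rate=0.0, seed=2,
        )
        snp, _, truth = simulate_population(cfg)
        # wipe line 2's segments: force its calls to recipient
        snp.calls["A01"][1, :] = CALL_RECIPIENT
        _, segs = infer_segments(snp, cfg.genome)
        assert not [s for s in segs if s.line == "L002"]
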