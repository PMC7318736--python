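"""Block partitioning and the stepwise likelihood-ratio QTL scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csslkit.genome import GenomeMap, IntrogressionSegment
from csslkit.genome_stats import union_coverage
from csslkit.qtl_blocks import (
    Block,
    QtlScanParams,
    carrier_matrix,
    partition_blocks,
    scan_qtl,
)

GENOME = GenomeMap(names=("A01",), bp={"A01": 20_000_000})


def _seg(line, start, end, state="donor_hom", chrom="A01"):
    return IntrogressionSegment(line=line, chrom=chrom, start=start, end=end, state=state)


class TestPartition:
    def test_overlapping_segments_cut_at_boundaries(self):
        segs = [_seg("A", 0, 10_000_000), _seg("B", 5_000_000, 15_000_000)]
        blocks = partition_blocks(segs, GENOME)
        spans = [(b.start, b.end, frozenset(b.dosage)) for b in blocks]
        assert spans == [
            (0, 5_000_000, frozenset({"A"})),
            (5_000_000, 10_000_000, frozenset({"A", "B"})),
            (10_000_000, 15_000_000, frozenset({"B"})),
        ]

    def test_single_segment_single_block(self):
        blocks = partition_blocks([_seg("A", 1_000_000, 2_000_000)], GENOME)
        assert len(blocks) == 1
        assert blocks[0].dosage == {"A": 1.0}

    def test_identical_segments_merge_into_one_block(self):
        segs = [_seg("A", 0, 1_000_000), _seg("B", 0, 1_000_000)]
        blocks = partition_blocks(segs, GENOME)
        assert len(blocks) == 1
        assert blocks[0].dosage == {"A": 1.0, "B": 1.0}

    def test_het_segment_gets_half_dosage(self):
        blocks = partition_blocks([_seg("A", 0, 1_000_000, state="het")], GENOME)
        assert blocks[0].dosage == {"A": 0.5}

    def test_invariant_to_segment_order(self):
        segs = [_seg("A", 0, 10_000_000), _seg("B", 5_000_000, 15_000_000),
                _seg("C", 2_000_000, 3_000_000, state="het")]
        a = partition_blocks(segs, GENOME)
        b = partition_blocks(list(reversed(segs)), GENOME)
        assert [(x.start, x.end, x.dosage) for x in a] == [(x.start, x.end, x.dosage) for x in b]

    def test_block_lengths_sum_to_union_coverage(self):
        segs = [_seg("A", 0, 10_000_000), _seg("B", 5_000_000, 15_000_000),
                _seg("C", 18_000_000, 19_000_000)]
        blocks = partition_blocks(segs, GENOME)
        total = sum(b.length for b in blocks)
        report = union_coverage(segs, GENOME)
        assert total == report[report.chrom == "A01"].iloc[0].union_length

    def test_block_ids_follow_genome_order(self):
        genome = GenomeMap(names=("A01", "D01"), bp={"A01": 10**7, "D01": 10**7})
        segs = [_seg("A", 0, 10**6, chrom="D01"), _seg("A", 0, 10**6, chrom="A01")]
        blocks = partition_blocks(segs, genome)
        assert [b.id for b in blocks] == ["block1", "block2"]
        assert [b.chrom for b in blocks] == ["A01", "D01"]


def _blocks(n, n_lines, carriers_per_block, rng):
    lines = tuple(f"L{i:03d}" for i in range(n_lines))
    blocks = []
    for b in range(n):
        chosen = rng.choice(n_lines, carriers_per_block, replace=False)
        blocks.append(
            Block(id=f"block{b+1}", chrom="A01", start=b * 10**6, end=(b + 1) * 10**6,
                  dosage={lines[i]: 1.0 for i in chosen})
        )
    return lines, blocks


class TestScan:
    def test_separable_case_capped_lod_and_exact_effect(self):
        lines = tuple(f"L{i}" for i in range(20))
        blk = Block(id="block1", chrom="A01", start=0, end=10**6,
                    dosage={l: 1.0 for l in lines[:10]})
        y = pd.Series([1.0] * 10 + [-1.0] * 10, index=lines, name="t")
        res = scan_qtl([blk], y, QtlScanParams())
        assert len(res) == 1
        row = res.iloc[0]
        assert row.lod == 50.0  # capped
        assert row.additive_effect == pytest.approx(1.0)
        assert row.qtl == "q-TA01"

    def test_lod_equals_f_statistic_mapping(self):
        """LOD = (n/2) log10(RSS0/RSS1) must equal (n/2) log10(1 + F/dfe)
        for the same single-block fit."""
        rng = np.random.default_rng(3)
        lines, blocks = _blocks(1, 100, 30, rng)
        x = blocks[0].dosage_vector(lines)
        y = 0.8 * x + rng.normal(0, 1, 100)
        res = scan_qtl(blocks, pd.Series(y, index=lines, name="t"),
                       QtlScanParams(lod_threshold=0.0))
        lod = res.iloc[0].lod
        # independent route: classical regression F test
        slope, intercept, r, p, se = stats.linregress(x, y)
        n = len(y)
        f = (r**2) * (n - 2) / (1 - r**2)
        lod_from_f = (n / 2) * np.log10(1 + f / (n - 2))
        assert lod == pytest.approx(lod_from_f, abs=0.01)
        assert res.iloc[0].additive_effect == pytest.approx(slope / 2, abs=1e-3)

    def test_pve_bounded_and_sums_below_100_for_orthogonal_blocks(self):
        """Noise-free signal from two disjoint carrier sets: each block's
        PVE <= 100 and their sum <= 100."""
        lines = tuple(f"L{i}" for i in range(30))
        b1 = Block(id="block1", chrom="A01", start=0, end=10**6,
                   dosage={l: 1.0 for l in lines[:10]})
        b2 = Block(id="block2", chrom="A01", start=2 * 10**6, end=3 * 10**6,
                   dosage={l: 1.0 for l in lines[10:20]})
        x1, x2 = b1.dosage_vector(lines), b2.dosage_vector(lines)
        y = pd.Series(2.0 * x1 - 1.0 * x2, index=lines, name="t")
        res = scan_qtl([b1, b2], y, QtlScanParams(lod_threshold=0.0))
        assert (res.pve_pct <= 100.0).all()
        assert res.pve_pct.sum() <= 100.0 + 1e-6

    def test_constant_dosage_block_skipped(self, caplog):
        lines = ("L1", "L2", "L3", "L4")
        full = Block(id="block1", chrom="A01", start=0, end=10**6,
                     dosage={l: 1.0 for l in lines})
        ok = Block(id="block2", chrom="A01", start=2 * 10**6, end=3 * 10**6,
                   dosage={"L1": 1.0, "L2": 1.0})
        y = pd.Series([1.0, 1.2, -1.0, -1.1], index=lines, name="t")
        res = scan_qtl([full, ok], y, QtlScanParams(lod_threshold=0.0))
        assert set(res.block) <= {"block2"}

    def test_collinear_duplicate_block_dropped(self):
        lines = tuple(f"L{i}" for i in range(30))
        d = {l: 1.0 for l in lines[:12]}
        b1 = Block(id="block1", chrom="A01", start=0, end=10**6, dosage=dict(d))
        b2 = Block(id="block2", chrom="A01", start=2 * 10**6, end=3 * 10**6, dosage=dict(d))
        rng = np.random.default_rng(0)
        y = pd.Series(2.0 * b1.dosage_vector(lines) + rng.normal(0, 0.5, 30),
                      index=lines, name="t")
        res = scan_qtl([b1, b2], y, QtlScanParams(lod_threshold=0.0))
        assert list(res.block) == ["block1"]

    def test_sign_orientation_flag(self):
        lines = tuple(f"L{i}" for i in range(20))
        blk = Block(id="block1", chrom="A01", start=0, end=10**6,
                    dosage={l: 1.0 for l in lines[:10]})
        y = pd.Series([1.0] * 10 + [-1.0] * 10, index=lines, name="t")
        a_pos = scan_qtl([blk], y, QtlScanParams(donor_positive=True)).iloc[0].additive_effect
        a_neg = scan_qtl([blk], y, QtlScanParams(donor_positive=False)).iloc[0].additive_effect
        assert a_pos == -a_neg == pytest.approx(1.0)

    def test_qtl_names_get_ordinal_suffix_per_chromosome(self):
        lines = tuple(f"L{i}" for i in range(40))
        rng = np.random.default_rng(5)
        b1 = Block(id="block1", chrom="A01", start=0, end=10**6,
                   dosage={l: 1.0 for l in lines[:10]})
        b2 = Block(id="block2", chrom="A01", start=2 * 10**6, end=3 * 10**6,
                   dosage={l: 1.0 for l in lines[20:30]})
        y = pd.Series(3.0 * b1.dosage_vector(lines) - 3.0 * b2.dosage_vector(lines)
                      + rng.normal(0, 0.3, 40), index=lines, name="fl")
        res = scan_qtl([b1, b2], y)
        assert list(res.qtl) == ["q-FLA01-1", "q-FLA01-2"]

    def test_permuted_phenotypes_lose_the_signal(self):
        """With a strong planted QTL, the max LOD on permuted phenotypes is
        (stochastically) below the unpermuted max LOD."""
        rng = np.random.default_rng(11)
        lines, blocks = _blocks(5, 200, 40, rng)
        x = blocks[2].dosage_vector(lines)
        y = 1.5 * x + rng.normal(0, 1, 200)
        res = scan_qtl(blocks, pd.Series(y, index=lines, name="t"),
                       QtlScanParams(lod_threshold=0.0))
        lod_true = res.lod.max()
        wins = 0
        for k in range(10):
            perm = rng.permutation(y)
            res_p = scan_qtl(blocks, pd.Series(perm, index=lines, name="t"),
                             QtlScanParams(lod_threshold=0.0))
            if lod_true > (res_p.lod.max() if len(res_p) else 0.0):
                wins += 1
        assert wins >= 9


def test_carrier_matrix_layout():
    lines = ("L1", "L2", "L3")
    blk = Block(id="block1", chrom="A01", start=0, end=10**6,
                dosage={"L1": 1.0, "L3": 0.5})
    m = carrier_matrix([blk], lines)
    assert list(m["block1"]) == [1.0, 0.0, 0.5]
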