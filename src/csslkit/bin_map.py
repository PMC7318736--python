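"""Sliding-window SNP genotyping and recombination-bin map construction.

A re-sequenced introgression-line population is genotyped against its two
parents: every SNP call is first reduced to donor / recipient / het /
missing, windows sliding along each chromosome are genotyped by a majority
rule, runs of equal window genotype become recombination bins, and donor or
heterozygous bins become introgression segments (the "GR-map").

The window rule: a window is called homozygous for a parent when more than
``majority_threshold`` (default 80%) of its genotyped SNPs carry that
parent's allele; otherwise it is heterozygous.  Windows with too few
informative SNPs are NA.  Adjacent same-genotype bins separated by less
than ``merge_gap`` are fused, and bins shorter than ``min_bin`` are
discarded, so the resulting map is robust to isolated miscalls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import DONOR_HOM, HET, NA, RECIPIENT_HOM, GenomeMap, IntrogressionSegment

logger = logging.getLogger(__name__)

# per-SNP call codes (int8)
CALL_MISSING = -1
CALL_RECIPIENT = 0
CALL_HET = 1
CALL_DONOR = 2

# per-window call codes reuse the SNP codes; CALL_MISSING doubles as NA
_WINDOW_GENOTYPE = {
    CALL_DONOR: DONOR_HOM,
    CALL_RECIPIENT: RECIPIENT_HOM,
    CALL_HET: HET,
    CALL_MISSING: NA,
}
_GENOTYPE_CODE = {v: k for k, v in _WINDOW_GENOTYPE.items()}


@dataclass
class SnpTable:
    """Per-line SNP genotype calls relative to the two parents.

    ``positions[chrom]`` is a sorted int64 array of 0-based positions;
    ``calls[chrom]`` is an int8 matrix of shape (n_lines, n_snps) holding
    :data:`CALL_DONOR` / :data:`CALL_RECIPIENT` / :data:`CALL_HET` /
    :data:`CALL_MISSING`.  ``alleles[chrom]``, when present, holds the
    (recipient, donor) allele bases per SNP for VCF round-tripping.
    """

    lines: tuple[str, ...]
    chroms: tuple[str, ...]
    positions: dict[str, np.ndarray]
    calls: dict[str, np.ndarray]
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        for chrom in self.chroms:
            pos = np.asarray(self.positions[chrom], dtype=np.int64)
            if np.any(np.diff(pos) <= 0):
                order = np.argsort(pos, kind="mergesort")
                pos = pos[order]
                self.calls[chrom] = np.asarray(self.calls[chrom])[:, order]
                if self.alleles is not None and chrom in self.alleles:
                    r, d = self.alleles[chrom]
                    self.alleles[chrom] = (np.asarray(r)[order], np.asarray(d)[order])
                if np.any(np.diff(pos) == 0):
                    raise ValueError(f"duplicate SNP positions on {chrom}")
                logger.warning("SNP positions on %s were unsorted; sorted", chrom)
            self.positions[chrom] = pos
            calls = np.asarray(self.calls[chrom], dtype=np.int8)
            if calls.shape != (len(self.lines), len(pos)):
                raise ValueError(
                    f"calls shape {calls.shape} != (n_lines={len(self.lines)}, n_snps={len(pos)}) on {chrom}"
                )
            self.calls[chrom] = calls

    @property
    def n_snps(self) -> int:
        return int(sum(len(self.positions[c]) for c in self.chroms))

    def line_index(self, line: str) -> int:
        try:
            return self.lines.index(line)
        except ValueError:
            raise KeyError(f"unknown line {line!r}") from None

    def equals(self, other: "SnpTable") -> bool:
        if self.lines != other.lines or self.chroms != other.chroms:
            return False
        return all(
            np.array_equal(self.positions[c], other.positions[c])
            and np.array_equal(self.calls[c], other.calls[c])
            for c in self.chroms
        )


@dataclass(frozen=True)
class BinCallingParams:
    """Tuning parameters of the sliding-window bin caller.

    Defaults: 50 kb windows stepped every 5 kb, 80% majority rule, bins and
    merge gaps of 100 kb, at least 5 informative SNPs per window.
    """

    window_size: int = 50_000
    step: int = 5_000
    majority_threshold: float = 0.8
    min_bin: int = 100_000
    merge_gap: int = 100_000
    min_snps_per_window: int = 5

    def __post_init__(self) -> None:
        if self.step > self.window_size:
            raise ValueError("step must be <= window_size")
        if not (0.5 < self.majority_threshold <= 1.0):
            raise ValueError("majority_threshold must lie in (0.5, 1]")
        if min(self.window_size, self.step) <= 0 or min(self.min_bin, self.merge_gap) < 0:
            raise ValueError("window/step must be positive, min_bin/merge_gap non-negative")


@dataclass(frozen=True)
class Bin:
    """A recombination bin: maximal interval of constant inferred genotype."""

    line: str
    chrom: str
    start: int
    end: int
    genotype: str
    n_snps: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty bin [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def filter_alleles(
    genotypes: np.ndarray,
    recipient: np.ndarray,
    donor: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce raw allele-pair genotypes to parental call codes.

    Parameters
    ----------
    genotypes
        Object array (n_lines, n_snps) of "X/Y" allele strings (or '.' for
        missing alleles).
    recipient, donor
        Parent allele per SNP (length n_snps).  Sites where the parents are
        identical are dropped (they carry no ancestry information); if the
        parents are identical genome-wide the input cannot be genotyped and
        a ValueError is raised.

    Returns
    -------
    (keep, calls)
        Boolean mask of retained SNPs and the int8 call matrix over them.
        A line call whose alleles match neither parent is set missing.
    """
    recipient = np.asarray(recipient, dtype=object)
    donor = np.asarray(donor, dtype=object)
    keep = recipient != donor
    if not keep.any():
        raise ValueError("parent columns are identical genome-wide")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d SNPs monomorphic between parents", n_dropped)

    geno = np.asarray(genotypes, dtype=object)[:, keep]
    rec = recipient[keep]
    don = donor[keep]
    calls = np.full(geno.shape, CALL_MISSING, dtype=np.int8)
    for i in range(geno.shape[0]):
        for j in range(geno.shape[1]):
            g = geno[i, j]
            if not g or g in (".", "./.", ".|."):
                continue
            a = g.replace("|", "/").split("/")
            if len(a) != 2 or "." in a:
                continue
            n_d = (a[0] == don[j]) + (a[1] == don[j])
            n_r = (a[0] == rec[j]) + (a[1] == rec[j])
            if n_d + n_r < 2:  # at least one allele matches neither parent
                continue
            calls[i, j] = {0: CALL_RECIPIENT, 1: CALL_HET, 2: CALL_DONOR}[n_d]
    return keep, calls


def window_starts(chrom_length: int, params: BinCallingParams) -> np.ndarray:
    """Window anchor positions: one window every ``step`` bp from 0."""
    return np.arange(0, chrom_length, params.step, dtype=np.int64)


def call_windows(
    positions: np.ndarray,
    calls: np.ndarray,
    chrom_length: int,
    params: BinCallingParams,
) -> np.ndarray:
    """Genotype sliding windows for one chromosome, all lines at once.

    ``calls`` is (n_lines, n_snps).  Returns an int8 matrix
    (n_lines, n_windows) of window codes.  The donor/recipient fraction is
    taken over all genotyped SNPs in the window (donor + recipient + het);
    heterozygous calls count toward neither parent, so a window dominated
    by het calls is called het rather than NA.
    """
    if len(positions) == 0 or chrom_length <= 0:
        return np.empty((calls.shape[0] if calls.ndim == 2 else 0, 0), dtype=np.int8)
    calls = np.atleast_2d(calls)
    starts = window_starts(chrom_length, params)
    ends = np.minimum(starts + params.window_size, chrom_length)
    i0 = np.searchsorted(positions, starts, side="left")
    i1 = np.searchsorted(positions, ends, side="left")

    out = np.full((calls.shape[0], len(starts)), CALL_MISSING, dtype=np.int8)
    # cumulative per-class counts -> O(1) per window
    for code, is_code in (
        (CALL_DONOR, calls == CALL_DONOR),
        (CALL_RECIPIENT, calls == CALL_RECIPIENT),
        (CALL_HET, calls == CALL_HET),
    ):
        cum = np.zeros((calls.shape[0], len(positions) + 1), dtype=np.int32)
        np.cumsum(is_code, axis=1, out=cum[:, 1:])
        if code == CALL_DONOR:
            n_d = cum[:, i1] - cum[:, i0]
        elif code == CALL_RECIPIENT:
            n_r = cum[:, i1] - cum[:, i0]
        else:
            n_h = cum[:, i1] - cum[:, i0]
    tot = n_d + n_r + n_h
    informative = tot >= params.min_snps_per_window
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_d = np.where(tot > 0, n_d / np.maximum(tot, 1), 0.0)
        frac_r = np.where(tot > 0, n_r / np.maximum(tot, 1), 0.0)
    thr = params.majority_threshold
    out[informative] = CALL_HET
    out[informative & (frac_d > thr)] = CALL_DONOR
    out[informative & (frac_r > thr)] = CALL_RECIPIENT
    return out


def windows_to_bins(
    window_calls: np.ndarray,
    chrom_length: int,
    params: BinCallingParams,
    line: str,
    chrom: str,
    positions: np.ndarray | None = None,
    snp_calls: np.ndarray | None = None,
) -> list[Bin]:
    """Collapse a line's window calls into tiling recombination bins.

    Maximal runs of equal window genotype become bins.  The breakpoint
    between two runs is placed at the midpoint of the overlap between the
    last window of the left run and the first window of the right run
    (equivalently, the midpoint of the two window centers).  The first bin
    starts at 0 and the last ends at the chromosome length, so bins always
    tile the chromosome exactly.
    """
    w = np.asarray(window_calls, dtype=np.int8).ravel()
    if w.size == 0:
        return []
    starts = window_starts(chrom_length, params)
    ends = np.minimum(starts + params.window_size, chrom_length)

    change = np.nonzero(np.diff(w))[0]  # run ends at index j, next run starts j+1
    bounds = [0]
    for j in change:
        # overlap of window j and window j+1: [starts[j+1], ends[j])
        mid = int((starts[j + 1] + ends[j]) // 2)
        mid = max(bounds[-1] + 1, min(mid, chrom_length - 1))
        bounds.append(mid)
    bounds.append(chrom_length)

    run_starts = np.concatenate([[0], change + 1])
    bins = []
    for k, ws_idx in enumerate(run_starts):
        s, e = bounds[k], bounds[k + 1]
        n = 0
        if positions is not None and snp_calls is not None:
            lo, hi = np.searchsorted(positions, [s, e], side="left")
            seg = snp_calls[lo:hi]
            n = int(np.count_nonzero(seg != CALL_MISSING))
        bins.append(Bin(line=line, chrom=chrom, start=s, end=e, genotype=_WINDOW_GENOTYPE[int(w[ws_idx])], n_snps=n))
    return bins


def _coalesce(bins: list[Bin]) -> list[Bin]:
    """Fuse adjacent bins of identical genotype (tiling preserved)."""
    out: list[Bin] = []
    for b in bins:
        if out and out[-1].genotype == b.genotype and out[-1].end == b.start:
            out[-1] = replace(out[-1], end=b.end, n_snps=out[-1].n_snps + b.n_snps)
        else:
            out.append(b)
    return out


def merge_and_filter(bins: list[Bin], params: BinCallingParams) -> list[Bin]:
    """Apply the merge/filter rules to one line-chromosome bin tiling.

    1. Two bins of the same genotype separated by less than ``merge_gap``
       are fused, absorbing whatever lies between them.
    2. Bins shorter than ``min_bin`` are set NA.
    3. Adjacent same-genotype bins are re-fused.

    Iterated to a fixed point, so the operation is idempotent.
    """
    if not bins:
        return []
    cur = sorted(bins, key=lambda b: b.start)
    for _ in range(20):
        new = _merge_filter_pass(cur, params)
        if [(b.start, b.end, b.genotype) for b in new] == [(b.start, b.end, b.genotype) for b in cur]:
            return new
        cur = new
    return cur


def _merge_filter_pass(bins: list[Bin], params: BinCallingParams) -> list[Bin]:
    bins = _coalesce(bins)
    # merge across short gaps: look back to the most recent same-genotype bin
    out: list[Bin] = []
    for b in bins:
        merged = False
        if b.genotype != NA:
            for j in range(len(out) - 1, -1, -1):
                if out[j].genotype == b.genotype:
                    if b.start - out[j].end < params.merge_gap:
                        out[j] = replace(out[j], end=b.end, n_snps=out[j].n_snps + b.n_snps)
                        del out[j + 1 :]
                        merged = True
                    break
        if not merged:
            out.append(b)
    # short-bin filter
    filtered = [
        b if (b.genotype == NA or b.length >= params.min_bin) else replace(b, genotype=NA)
        for b in out
    ]
    return _coalesce(filtered)


def bins_to_segments(bins: list[Bin]) -> list[IntrogressionSegment]:
    """Donor-homozygous and heterozygous bins become introgression segments."""
    return [
        IntrogressionSegment(line=b.line, chrom=b.chrom, start=b.start, end=b.end, state=b.genotype)
        for b in bins
        if b.genotype in (DONOR_HOM, HET)
    ]


def infer_segments(
    table: SnpTable,
    genome: GenomeMap,
    params: BinCallingParams | None = None,
) -> tuple[list[Bin], list[IntrogressionSegment]]:
    """Full GR-map pipeline: windows -> bins -> merge/filter -> segments.

    Returns the merged/filtered bins of every line and the introgression
    segments derived from them.
    """
    params = params or BinCallingParams()
    all_bins: list[Bin] = []
    segments: list[IntrogressionSegment] = []
    for chrom in table.chroms:
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} absent from genome map")
        pos = table.positions[chrom]
        calls = table.calls[chrom]
        length = genome.bp[chrom]
        wcalls = call_windows(pos, calls, length, params)
        for i, line in enumerate(table.lines):
            raw = windows_to_bins(
                wcalls[i], length, params, line=line, chrom=chrom, positions=pos, snp_calls=calls[i]
            )
            merged = merge_and_filter(raw, params)
            all_bins.extend(merged)
            segments.extend(bins_to_segments(merged))
    return all_bins, segments
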