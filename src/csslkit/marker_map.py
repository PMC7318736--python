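"""Introgression-segment reconstruction from SSR graphical genotypes.

Each line is scored at sparse SSR markers as DD (homozygous donor), DR
(heterozygous) or RR (homozygous recipient).  An interval flanked by two
DD markers is counted as 100% donor, a DD<->RR transition interval (with or
without a DR marker inside) as 50%, and RR-flanked intervals as 0%.  The
estimated segment length is therefore the DD span plus half of each flank
("MM-map" estimator).  Missing marker calls never break a run; they are
spanned and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genome import DONOR_HOM, HET, GenomeMap
from .synthetic import MarkerTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerSegment:
    """One marker-inferred introgression segment.

    ``core_start``/``core_end`` span the outermost DD markers (equal to the
    outermost DR markers for het-only segments); ``flank_start``/
    ``flank_end`` are the bounding RR markers or chromosome ends.  Positions
    are cM.  ``length`` is the DD span plus half of each flank (a terminal
    flank with a DD core counts at full weight).  ``state`` is donor-hom if
    the run contains at least one DD marker, else het.
    """

    line: str
    chrom: str
    core_start: float
    core_end: float
    flank_start: float
    flank_end: float
    length: float
    state: str
    n_missing_spanned: int = 0


def _runs(codes: list[str | None]) -> list[tuple[int, int]]:
    """Maximal runs of non-RR informative calls; missing is transparent.

    Returns (first_idx, last_idx) pairs over marker indices, where the run
    contains at least one DD or DR call and no RR call between them.
    """
    runs = []
    start = None
    last_inf = None
    for i, c in enumerate(codes):
        if c in ("DD", "DR"):
            if start is None:
                start = i
            last_inf = i
        elif c == "RR":
            if start is not None:
                runs.append((start, last_inf))
                start = None
        # None (missing): transparent
    if start is not None:
        runs.append((start, last_inf))
    return runs


def call_marker_segments(table: MarkerTable, genome: GenomeMap) -> list[MarkerSegment]:
    """One MarkerSegment per maximal run of non-RR calls per line and
    chromosome.  Lines with all calls missing yield no segments (warned)."""
    segments: list[MarkerSegment] = []
    for chrom, grp in table.markers.groupby("chrom", sort=False):
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} absent from genome map")
        if len(grp) < 2:
            raise ValueError(f"need at least 2 markers on {chrom}")
        ids = list(grp["marker"])
        pos = list(grp["cm"].astype(float))
        chrom_len = genome.cm[chrom] if genome.cm is not None else max(pos)
        for line in table.calls.index:
            row = table.calls.loc[line, ids]
            codes = [c if isinstance(c, str) else None for c in row]
            if all(c is None for c in codes):
                logger.warning("line %s has no marker calls on %s", line, chrom)
                continue
            for first, last in _runs(codes):
                seg = _estimate_segment(line, chrom, codes, pos, first, last, chrom_len)
                segments.append(seg)
    return segments


def _estimate_segment(
    line: str,
    chrom: str,
    codes: list[str | None],
    pos: list[float],
    first: int,
    last: int,
    chrom_len: float,
) -> MarkerSegment:
    dd_idx = [i for i in range(first, last + 1) if codes[i] == "DD"]
    state = DONOR_HOM if dd_idx else HET
    if dd_idx:
        core_lo, core_hi = pos[dd_idx[0]], pos[dd_idx[-1]]
    else:
        core_lo, core_hi = pos[first], pos[last]

    # bounding RR markers (or chromosome ends)
    left_rr = next((i for i in range(first - 1, -1, -1) if codes[i] == "RR"), None)
    right_rr = next((i for i in range(last + 1, len(codes)) if codes[i] == "RR"), None)
    flank_lo = pos[left_rr] if left_rr is not None else 0.0
    flank_hi = pos[right_rr] if right_rr is not None else chrom_len

    # terminal flanks count at full weight for DD-anchored segments
    w_left = 0.5 if (left_rr is not None or not dd_idx) else 1.0
    w_right = 0.5 if (right_rr is not None or not dd_idx) else 1.0
    if dd_idx:
        length = (core_hi - core_lo) + w_left * (core_lo - flank_lo) + w_right * (flank_hi - core_hi)
    else:
        length = 0.5 * (flank_hi - flank_lo)
    length = min(max(length, 0.0), chrom_len)

    n_missing = sum(1 for i in range(first, last + 1) if codes[i] is None)
    if n_missing:
        logger.info("segment %s:%s spans %d missing marker calls", line, chrom, n_missing)
    return MarkerSegment(
        line=line,
        chrom=chrom,
        core_start=core_lo,
        core_end=core_hi,
        flank_start=flank_lo,
        flank_end=flank_hi,
        length=length,
        state=state,
        n_missing_spanned=n_missing,
    )


def mm_summary(segments: list[MarkerSegment], genome: GenomeMap) -> pd.DataFrame:
    """Per-chromosome segment counts and total estimated donor length (cM),
    plus a genome-wide Total row."""
    rows = []
    total_n, total_len = 0, 0.0
    for chrom in genome.names:
        segs = [s for s in segments if s.chrom == chrom]
        n = len(segs)
        donor_len = sum(s.length for s in segs)
        chrom_len = genome.cm[chrom] if genome.cm is not None else float("nan")
        rows.append((chrom, chrom_len, n, donor_len))
        total_n += n
        total_len += donor_len
    rows.append(("Total", genome.total_cm if genome.cm is not None else float("nan"), total_n, total_len))
    return pd.DataFrame(rows, columns=["chrom", "length_cm", "n_segments", "donor_length_cm"])


def marker_segments_to_frame(segments: list[MarkerSegment]) -> pd.DataFrame:
    """Tabulate marker segments (cM coordinates) for TSV export."""
    return pd.DataFrame(
        [
            (s.line, s.chrom, s.flank_start, s.core_start, s.core_end, s.flank_end, s.length, s.state, s.n_missing_spanned)
            for s in segments
        ],
        columns=[
            "line", "chrom", "flank_start_cm", "core_start_cm", "core_end_cm",
            "flank_end_cm", "est_length_cm", "state", "n_missing_spanned",
        ],
    )
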