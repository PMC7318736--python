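"""Genome coverage and marker/SNP density statistics.

Summarises how much of the donor genome a population of introgression
segments covers: per-chromosome interval unions, coverage rates, fold
coverage (total segment length over genome length, overlaps counted
multiply), and marker spacing / SNP density, aggregated per subgenome and
genome-wide in the layout of the study's comparison table.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeMap, subgenome_of


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero to mirror printed-report formatting."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def union_length(intervals: Iterable[tuple[float, float]]) -> float:
    """Total length of the union of (start, end) intervals."""
    ivs = sorted(intervals)
    total = 0.0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def coverage_rate(union_len: float, chrom_len: float) -> float:
    """Union coverage / map length as a percentage, rounded half-up to 2 dp."""
    return round_half_up(100.0 * union_len / chrom_len, 2)


def _check_bounds(chrom: str, s: float, e: float, length: float) -> None:
    if s < 0 or e > length:
        raise ValueError(f"segment [{s}, {e}) outside chromosome {chrom} bounds [0, {length})")


def union_coverage(
    segments,
    genome: GenomeMap,
    unit: str = "bp",
) -> pd.DataFrame:
    """Per-chromosome (plus subgenome and Total) coverage report.

    ``segments`` is an iterable of objects with chrom/start/end (physical
    unit='bp') or of MarkerSegment (unit='cm', using the estimator interval
    flank midpoints so the interval length matches the estimated length).
    Aggregate rows sum member unions before dividing, so the aggregate rate
    always lies between the member rates.
    """
    by_chrom: dict[str, list[tuple[float, float]]] = {c: [] for c in genome.names}
    counts = {c: 0 for c in genome.names}
    for s in segments:
        if s.chrom not in by_chrom:
            raise KeyError(f"chromosome {s.chrom!r} absent from genome map")
        iv = _segment_interval(s)
        length = genome.bp[s.chrom] if unit == "bp" else genome.cm[s.chrom]
        _check_bounds(s.chrom, iv[0], iv[1], length)
        by_chrom[s.chrom].append(iv)
        counts[s.chrom] += 1

    rows = []
    for chrom in genome.names:
        length = genome.bp[chrom] if unit == "bp" else genome.cm[chrom]
        u = union_length(by_chrom[chrom])
        rows.append(
            {
                "chrom": chrom,
                "subgenome": subgenome_of(chrom),
                "length": length,
                "n_segments": counts[chrom],
                "union_length": u,
                "coverage_rate_pct": coverage_rate(u, length),
            }
        )
    df = pd.DataFrame(rows)
    aggs = []
    for sub, grp in df.groupby("subgenome", sort=False):
        if sub is None:
            continue
        aggs.append(_agg_row(f"{sub} subgenome", grp))
    aggs.append(_agg_row("Total", df))
    return pd.concat([df, pd.DataFrame(aggs)], ignore_index=True)


def _agg_row(name: str, grp: pd.DataFrame) -> dict:
    length = grp["length"].sum()
    u = grp["union_length"].sum()
    return {
        "chrom": name,
        "subgenome": None,
        "length": length,
        "n_segments": int(grp["n_segments"].sum()),
        "union_length": u,
        "coverage_rate_pct": coverage_rate(u, length),
    }


def _segment_interval(s) -> tuple[float, float]:
    if hasattr(s, "start"):
        return (float(s.start), float(s.end))
    # MarkerSegment: effective interval from flank midpoints
    lo = (s.flank_start + s.core_start) / 2.0
    hi = (s.core_end + s.flank_end) / 2.0
    return (lo, hi)


def fold_coverage(segments, genome: GenomeMap, unit: str = "bp") -> float:
    """Sum of all segment lengths (overlaps counted multiply) over the total
    genome length."""
    total_len = genome.total_bp if unit == "bp" else genome.total_cm
    seg_sum = 0.0
    for s in segments:
        lo, hi = _segment_interval(s)
        seg_sum += hi - lo
    return seg_sum / total_len


def density_stats(
    counts: Mapping[str, int],
    genome: GenomeMap,
    mode: str = "marker",
) -> pd.DataFrame:
    """Marker spacing (cM/marker) or SNP density (SNPs/kb) per chromosome,
    subgenome, and Total, reported at 1 decimal place.

    ``counts`` maps chromosome -> number of markers or SNPs.  Chromosomes
    with zero markers report NA spacing.
    """
    if mode not in ("marker", "snp"):
        raise ValueError("mode must be 'marker' or 'snp'")
    rows = []
    for chrom in genome.names:
        n = int(counts.get(chrom, 0))
        rows.append({"chrom": chrom, "subgenome": subgenome_of(chrom), "n": n,
                     "length": genome.cm[chrom] if mode == "marker" else genome.bp[chrom]})
    df = pd.DataFrame(rows)
    aggs = []
    for sub, grp in df.groupby("subgenome", sort=False):
        if sub is None:
            continue
        aggs.append({"chrom": f"{sub} subgenome", "subgenome": None,
                     "n": int(grp["n"].sum()), "length": grp["length"].sum()})
    aggs.append({"chrom": "Total", "subgenome": None, "n": int(df["n"].sum()), "length": df["length"].sum()})
    df = pd.concat([df, pd.DataFrame(aggs)], ignore_index=True)
    if mode == "marker":
        df["spacing_cm_per_marker"] = [
            round_half_up(L / n, 1) if n > 0 else np.nan for L, n in zip(df["length"], df["n"])
        ]
    else:
        df["density_snps_per_kb"] = [
            round_half_up(n / (L / 1000.0), 1) for L, n in zip(df["length"], df["n"])
        ]
    return df


def marker_spacing(n_markers: int, map_length_cm: float) -> float:
    """Mean genetic-map spacing in cM per marker, 1 dp."""
    if n_markers <= 0:
        return float("nan")
    return round_half_up(map_length_cm / n_markers, 1)


def snp_density(n_snps: int, length_bp: float) -> float:
    """SNPs per kb, 1 dp."""
    return round_half_up(n_snps / (length_bp / 1000.0), 1)
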