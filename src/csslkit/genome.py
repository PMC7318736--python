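"""Core genomic containers shared across the pipeline.

Coordinates are 0-based half-open (BED convention) everywhere inside the
package; user-facing tables are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: genotype state codes used for segments and bins
DONOR_HOM = "donor_hom"
HET = "het"
RECIPIENT_HOM = "recipient_hom"
NA = "NA"

SEGMENT_STATES = (DONOR_HOM, HET)
BIN_GENOTYPES = (DONOR_HOM, RECIPIENT_HOM, HET, NA)


@dataclass(frozen=True)
class GenomeMap:
    """Ordered chromosomes with physical (bp) and optional genetic (cM) lengths.

    Parameters
    ----------
    names
        Chromosome names in genome order (e.g. ``A01..A13, D01..D13`` for an
        allotetraploid cotton-like genome).
    bp
        Physical length of each chromosome in base pairs.
    cm
        Genetic length in centimorgan; optional (``None`` when only a
        physical map is available).
    """

    names: tuple[str, ...]
    bp: dict[str, int] = field(default_factory=dict)
    cm: dict[str, float] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in self.names if c not in self.bp]
        if missing:
            raise ValueError(f"chromosomes without bp length: {missing}")
        if any(self.bp[c] <= 0 for c in self.names):
            raise ValueError("chromosome lengths must be positive")
        if self.cm is not None and any(c not in self.cm for c in self.names):
            raise ValueError("cm lengths missing for some chromosomes")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.bp

    @property
    def total_bp(self) -> int:
        return sum(self.bp[c] for c in self.names)

    @property
    def total_cm(self) -> float:
        if self.cm is None:
            raise ValueError("genome has no genetic map")
        return sum(self.cm[c] for c in self.names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.names, "length_bp": [self.bp[c] for c in self.names]})
        if self.cm is not None:
            df["length_cm"] = [self.cm[c] for c in self.names]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeMap":
        cm = None
        if "length_cm" in df.columns:
            cm = dict(zip(df["chrom"], df["length_cm"].astype(float)))
        return cls(
            names=tuple(df["chrom"]),
            bp=dict(zip(df["chrom"], df["length_bp"].astype(int))),
            cm=cm,
        )


@dataclass(frozen=True, order=True)
class IntrogressionSegment:
    """One donor interval in one line, physical coordinates.

    ``state`` is :data:`DONOR_HOM` for a homozygous donor segment or
    :data:`HET` for a heterozygous one.
    """

    line: str
    chrom: str
    start: int
    end: int
    state: str = DONOR_HOM

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty segment [{self.start}, {self.end})")
        if self.state not in SEGMENT_STATES:
            raise ValueError(f"invalid segment state {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def segments_to_frame(segments) -> pd.DataFrame:
    """Tabulate segments as a BED-like frame (chrom, start, end, line, state)."""
    rows = [(s.chrom, s.start, s.end, s.line, s.state) for s in segments]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "line", "state"])
    return df.sort_values(["chrom", "start", "end", "line"], kind="mergesort").reset_index(drop=True)


def frame_to_segments(df: pd.DataFrame) -> list[IntrogressionSegment]:
    return [
        IntrogressionSegment(
            line=str(r.line), chrom=str(r.chrom), start=int(r.start), end=int(r.end), state=str(r.state)
        )
        for r in df.itertuples(index=False)
    ]


# Physical chromosome lengths (Mb) of the 26 allotetraploid cotton
# chromosomes, used by the synthetic generator to build realistic
# scaled-down genomes.  Genetic lengths use ~2 cM/Mb, the genome-wide
# ratio of interspecific Gh x Gb maps.
COTTON_CHROM_MB = {
    "A01": 117.71, "A02": 108.05, "A03": 113.01, "A04": 85.11, "A05": 109.37,
    "A06": 124.01, "A07": 97.74, "A08": 122.33, "A09": 82.06, "A10": 114.80,
    "A11": 123.16, "A12": 107.62, "A13": 108.33,
    "D01": 63.18, "D02": 69.81, "D03": 52.68, "D04": 56.41, "D05": 62.90,
    "D06": 66.84, "D07": 59.23, "D08": 69.01, "D09": 52.80, "D10": 67.98,
    "D11": 72.91, "D12": 62.67, "D13": 63.32,
}


def cotton_like_genome(scale: float = 1.0, cm_per_mb: float = 2.0) -> GenomeMap:
    """A 26-chromosome allotetraploid genome, optionally scaled down.

    ``scale=1`` gives full-size (~2.2 Gb) chromosomes; smaller values give
    proportionally shrunken chromosomes for fast simulation.
    """
    names = tuple(COTTON_CHROM_MB)
    bp = {c: max(1, int(round(COTTON_CHROM_MB[c] * 1e6 * scale))) for c in names}
    cm = {c: bp[c] / 1e6 * cm_per_mb for c in names}
    return GenomeMap(names=names, bp=bp, cm=cm)


def subgenome_of(chrom: str) -> str | None:
    """Subgenome label ('At'/'Dt') for cotton-style chromosome names, else None."""
    if chrom.startswith("A"):
        return "At"
    if chrom.startswith("D"):
        return "Dt"
    return None
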