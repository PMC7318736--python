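"""Synthetic CSSL populations with known ground truth.

Generates a chromosome segment substitution line (CSSL) population the way
the downstream pipeline assumes it arises: each line is the recurrent
(recipient) parent's genome carrying a small number of planted donor
segments, some heterozygous.  Dense biallelic SNPs distinguish the two
parents; SSR-style markers sit on a sparse jittered grid with graphical
genotypes (DD/DR/RR).  Both are corrupted by configurable genotyping error
and missingness.  Phenotypes follow a block-additive QTL model with fixed
environment effects and random line and residual effects, so every stage of
the pipeline can be checked against the planted truth.

Segments are planted directly rather than simulated through the BC4-BC6
breeding scheme; the goal is the statistical structure the genotyping and
QTL machinery sees, not the pedigree that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bin_map import CALL_DONOR, CALL_HET, CALL_MISSING, CALL_RECIPIENT, SnpTable
from .genome import DONOR_HOM, HET, GenomeMap, IntrogressionSegment, cotton_like_genome

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic CSSL population.

    Defaults emulate a 1/10-scale allotetraploid cotton genome: 26
    chromosomes, 100 lines each carrying 1-10 donor segments (10%
    heterozygous), 5 SNPs/kb between parents, 1% genotyping error, 5%
    missing calls, SSR markers every ~1 Mb, five environments.
    """

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: dict(cotton_like_genome(scale=0.1).bp)
    )
    n_lines: int = 100
    segments_per_line: tuple[int, int] = (1, 10)
    segment_length: tuple[int, int] = (500_000, 10_000_000)
    het_fraction: float = 0.1
    snp_density: float = 5.0  # SNPs per kb
    genotyping_error: float = 0.01
    missing_rate: float = 0.05
    marker_spacing: int = 1_000_000  # mean bp between SSR markers
    min_segment_gap: int = 300_000  # keeps planted segments identifiable
    cm_per_mb: float = 2.0
    n_envs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for p, name in [
            (self.het_fraction, "het_fraction"),
            (self.genotyping_error, "genotyping_error"),
            (self.missing_rate, "missing_rate"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(v <= 0 for v in self.chromosome_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.n_envs < 1:
            raise ValueError("n_envs must be >= 1")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")
        if self.segment_length[0] > max(self.chromosome_lengths.values()):
            raise ValueError("minimum segment length exceeds the longest chromosome")
        if not (1 <= self.segments_per_line[0] <= self.segments_per_line[1]):
            raise ValueError("segments_per_line must satisfy 1 <= min <= max")

    @property
    def genome(self) -> GenomeMap:
        names = tuple(self.chromosome_lengths)
        bp = dict(self.chromosome_lengths)
        cm = {c: bp[c] / 1e6 * self.cm_per_mb for c in names}
        return GenomeMap(names=names, bp=bp, cm=cm)


@dataclass(frozen=True)
class QtlSpec:
    """A planted QTL: block id, trait, additive effect a (half the
    donor-hom minus recipient difference; genotypic value is 2a*x)."""

    block: str
    trait: str
    a: float


@dataclass
class TruthSet:
    """Ground truth of a simulated population: planted segments, planted
    QTL, and the variance components used for phenotypes."""

    segments: list[IntrogressionSegment]
    qtl: list[QtlSpec] = field(default_factory=list)
    var_g: float = 0.0
    var_e: float = 0.0
    var_env: float = 0.0

    def segments_of(self, line: str) -> list[IntrogressionSegment]:
        return [s for s in self.segments if s.line == line]


@dataclass
class MarkerTable:
    """SSR marker map plus per-line graphical genotypes.

    ``markers`` has columns (marker, chrom, cm, bp) sorted by position;
    ``calls`` is a lines x markers frame of 'DD'/'DR'/'RR' codes with NaN
    for missing.
    """

    markers: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            key = "cm" if "cm" in grp.columns and grp["cm"].notna().all() else "bp"
            if not grp[key].is_monotonic_increasing:
                raise ValueError(f"marker positions not increasing on {chrom}")
        bad = set(self.calls.stack().unique()) - {"DD", "DR", "RR"}
        if bad:
            raise ValueError(f"invalid marker calls: {sorted(bad)}")


def _line_names(n: int) -> tuple[str, ...]:
    return tuple(f"L{i + 1:03d}" for i in range(n))


def _plant_segments(config: SimConfig, rng: np.random.Generator) -> list[IntrogressionSegment]:
    chroms = list(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    lo, hi = config.segment_length
    segs: list[IntrogressionSegment] = []
    for line in _line_names(config.n_lines):
        n_seg = int(rng.integers(config.segments_per_line[0], config.segments_per_line[1] + 1))
        placed: dict[str, list[tuple[int, int]]] = {}
        for _ in range(n_seg):
            for _try in range(100):
                chrom = chroms[rng.choice(len(chroms), p=probs)]
                clen = config.chromosome_lengths[chrom]
                seg_len = int(rng.integers(lo, min(hi, clen) + 1))
                if seg_len > clen:
                    continue
                start = int(rng.integers(0, clen - seg_len + 1))
                end = start + seg_len
                pad = config.min_segment_gap
                if all(end + pad <= s or e + pad <= start for s, e in placed.get(chrom, [])):
                    placed.setdefault(chrom, []).append((start, end))
                    state = HET if rng.random() < config.het_fraction else DONOR_HOM
                    segs.append(IntrogressionSegment(line=line, chrom=chrom, start=start, end=end, state=state))
                    break
            else:
                raise RuntimeError(
                    f"could not place {n_seg} non-overlapping segments on line {line} in 100 tries"
                )
    return segs


def _truth_calls(positions: np.ndarray, segs: list[tuple[int, int, str]]) -> np.ndarray:
    """Noise-free per-SNP calls for one line on one chromosome."""
    calls = np.full(len(positions), CALL_RECIPIENT, dtype=np.int8)
    for start, end, state in segs:
        lo, hi = np.searchsorted(positions, [start, end], side="left")
        calls[lo:hi] = CALL_DONOR if state == DONOR_HOM else CALL_HET
    return calls


def _corrupt(calls: np.ndarray, error: float, missing: float, rng: np.random.Generator) -> np.ndarray:
    """Miscall each genotype with prob ``error`` (uniform over the two other
    states, so the realized mismatch rate equals ``error``), then drop to
    missing with prob ``missing``."""
    out = calls.copy()
    if error > 0:
        flip = rng.random(out.shape) < error
        # the two states != current one, chosen uniformly
        shift = rng.integers(1, 3, size=out.shape).astype(np.int8)
        out[flip] = (out[flip] + shift[flip]) % 3
    if missing > 0:
        out[rng.random(out.shape) < missing] = CALL_MISSING
    return out


def simulate_population(config: SimConfig) -> tuple[SnpTable, MarkerTable, TruthSet]:
    """Generate SNP calls, SSR marker genotypes, and the planted truth.

    Deterministic given ``config.seed``.  Inside a planted donor-homozygous
    segment every SNP carries the donor allele (het segments yield het
    calls); elsewhere the recipient allele — before corruption by the
    configured error and missing rates.
    """
    rng = np.random.default_rng(config.seed)
    genome = config.genome
    lines = _line_names(config.n_lines)
    truth_segments = _plant_segments(config, rng)

    by_line_chrom: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for s in truth_segments:
        by_line_chrom.setdefault((s.line, s.chrom), []).append((s.start, s.end, s.state))

    positions: dict[str, np.ndarray] = {}
    calls: dict[str, np.ndarray] = {}
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    marker_rows = []
    marker_calls: dict[str, list] = {line: [] for line in lines}
    marker_ids = []

    for chrom in genome.names:
        clen = genome.bp[chrom]
        n_snps = max(1, int(round(config.snp_density * clen / 1000.0)))
        pos = np.sort(rng.choice(clen, size=min(n_snps, clen), replace=False)).astype(np.int64)
        positions[chrom] = pos
        # recipient and donor alleles always differ
        rec = _BASES[rng.integers(0, 4, size=len(pos))]
        don = _BASES[(np.char.find("ACGT", rec) + rng.integers(1, 4, size=len(pos))) % 4]
        alleles[chrom] = (rec, don)

        mat = np.empty((len(lines), len(pos)), dtype=np.int8)
        for i, line in enumerate(lines):
            truth = _truth_calls(pos, by_line_chrom.get((line, chrom), []))
            mat[i] = _corrupt(truth, config.genotyping_error, config.missing_rate, rng)
        calls[chrom] = mat

        # SSR markers on a jittered grid anchored at the chromosome ends
        n_mark = max(2, int(round(clen / config.marker_spacing)) + 1)
        grid = np.linspace(0, clen - 1, n_mark)
        jitter = np.zeros(n_mark)
        if n_mark > 2:
            jitter[1:-1] = rng.uniform(-0.25, 0.25, size=n_mark - 2) * clen / (n_mark - 1)
        mpos = np.clip(np.sort((grid + jitter).astype(np.int64)), 0, clen - 1)
        mpos = np.unique(mpos)
        for k, p in enumerate(mpos):
            mid = f"{chrom}_M{k + 1:03d}"
            marker_ids.append(mid)
            marker_rows.append((mid, chrom, p / 1e6 * config.cm_per_mb, int(p)))
        code_to_str = {CALL_DONOR: "DD", CALL_HET: "DR", CALL_RECIPIENT: "RR", CALL_MISSING: None}
        for i, line in enumerate(lines):
            truth = _truth_calls(mpos, by_line_chrom.get((line, chrom), []))
            noisy = _corrupt(truth, config.genotyping_error, config.missing_rate, rng)
            marker_calls[line].extend(code_to_str[int(c)] for c in noisy)

    snp_table = SnpTable(
        lines=lines, chroms=genome.names, positions=positions, calls=calls, alleles=alleles
    )
    markers = pd.DataFrame(marker_rows, columns=["marker", "chrom", "cm", "bp"])
    calls_df = pd.DataFrame.from_dict(marker_calls, orient="index", columns=marker_ids)
    marker_table = MarkerTable(markers=markers, calls=calls_df)
    return snp_table, marker_table, TruthSet(segments=truth_segments)


def simulate_trait(
    n_lines: int,
    n_envs: int,
    var_g: float,
    var_e: float,
    var_env: float = 1.0,
    mu: float = 0.0,
    genetic_values: np.ndarray | None = None,
    seed: int = 0,
    trait: str = "trait1",
    lines: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """One trait under y_ij = mu + env_j + G_i + g_i + e_ij (long format).

    ``genetic_values`` (length n_lines) carries any fixed genetic signal,
    e.g. planted QTL effects; ``g_i ~ N(0, var_g)`` is the polygenic line
    effect and ``e_ij ~ N(0, var_e)`` the residual.
    """
    rng = np.random.default_rng(seed)
    lines = lines or _line_names(n_lines)
    envs = [f"E{j + 1}" for j in range(n_envs)]
    env_eff = rng.normal(0.0, np.sqrt(var_env), size=n_envs) if var_env > 0 else np.zeros(n_envs)
    g = rng.normal(0.0, np.sqrt(var_g), size=n_lines) if var_g > 0 else np.zeros(n_lines)
    G = np.zeros(n_lines) if genetic_values is None else np.asarray(genetic_values, dtype=float)
    rows = []
    for j, env in enumerate(envs):
        e = rng.normal(0.0, np.sqrt(var_e), size=n_lines) if var_e > 0 else np.zeros(n_lines)
        y = mu + env_eff[j] + G + g + e
        rows.extend(zip(lines, [env] * n_lines, [trait] * n_lines, y))
    return pd.DataFrame(rows, columns=["line", "env", "trait", "value"])


def simulate_phenotypes(
    truth: TruthSet,
    blocks,
    qtl: list[QtlSpec],
    lines: tuple[str, ...],
    n_envs: int = 5,
    var_g: float = 0.0,
    var_e: float = 1.0,
    var_env: float = 1.0,
    mu: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotypes under the block-additive model y_ij = mu + env_j +
    sum_b 2*a_b*x_ib + g_i + e_ij, with donor dosage x in {0, 0.5, 1}.

    ``blocks`` is the list of population Blocks (see qtl_blocks); every
    planted QTL must reference an existing block id.  The QTL plan and
    variance components are recorded into ``truth``.
    """
    block_by_id = {b.id: b for b in blocks}
    for q in qtl:
        if q.block not in block_by_id:
            raise KeyError(f"planted QTL references unknown block id {q.block!r}")
    truth.qtl = list(qtl)
    truth.var_g, truth.var_e, truth.var_env = var_g, var_e, var_env

    traits = sorted({q.trait for q in qtl}) or ["trait1"]
    frames = []
    for t_idx, trait in enumerate(traits):
        G = np.zeros(len(lines))
        for q in qtl:
            if q.trait != trait:
                continue
            blk = block_by_id[q.block]
            for i, line in enumerate(lines):
                G[i] += 2.0 * q.a * blk.dosage.get(line, 0.0)
        frames.append(
            simulate_trait(
                n_lines=len(lines),
                n_envs=n_envs,
                var_g=var_g,
                var_e=var_e,
                var_env=var_env,
                mu=mu,
                genetic_values=G,
                seed=seed + 7919 * t_idx,
                trait=trait,
                lines=lines,
            )
        )
    return pd.concat(frames, ignore_index=True)
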