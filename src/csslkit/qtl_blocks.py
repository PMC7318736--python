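"""Block partitioning and the block-based stepwise likelihood-ratio QTL scan.

The population's introgression segments are cut at every segment boundary
into non-overlapping *blocks* within which each line's donor dosage
(0 = recipient, 0.5 = heterozygous, 1 = donor homozygous) is constant.
Blocks are the unit of QTL testing: line BLUPs are regressed on block
dosages, background cofactors are chosen by forward-backward stepwise
selection, and each block is then tested by a likelihood-ratio contrast of
the model with and without it:

    LOD_b = (n/2) * log10(RSS_reduced / RSS_full)

The additive effect a_b is half the fitted donor-hom minus recipient
difference (the regression coefficient on dosage divided by two), and PVE
is the share of the total phenotypic sum of squares the block explains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import DONOR_HOM, HET, GenomeMap

logger = logging.getLogger(__name__)

_DOSAGE = {DONOR_HOM: 1.0, HET: 0.5}


@dataclass
class Block:
    """A population-level interval with constant per-line donor dosage.

    ``dosage`` maps carrier line -> dosage in {0.5, 1.0}; non-carriers are
    implicit zeros.
    """

    id: str
    chrom: str
    start: int
    end: int
    dosage: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    def dosage_vector(self, lines) -> np.ndarray:
        return np.array([self.dosage.get(line, 0.0) for line in lines])


@dataclass(frozen=True)
class QtlScanParams:
    """Stepwise-scan tuning: entry/removal p-values for cofactor selection,
    the LOD report threshold, the numerical LOD cap for separable fits, and
    the sign orientation of reported additive effects (``donor_positive``:
    positive a means the donor allele increases the trait)."""

    p_in: float = 0.05
    p_out: float = 0.10
    lod_threshold: float = 2.5
    lod_cap: float = 50.0
    donor_positive: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.p_in <= self.p_out <= 1):
            raise ValueError("need 0 < p_in <= p_out <= 1")


def partition_blocks(segments, genome: GenomeMap) -> list[Block]:
    """Cut the genome at every segment boundary into blocks.

    Atomic intervals between consecutive boundaries get a per-line dosage
    vector; intervals carried by no line are dropped and contiguous
    intervals with identical dosage vectors are merged.  Output order (and
    block numbering) follows genome order; the result is invariant to the
    input order of segments.
    """
    blocks: list[Block] = []
    for chrom in genome.names:
        segs = sorted(
            (s for s in segments if s.chrom == chrom), key=lambda s: (s.start, s.end, s.line)
        )
        if not segs:
            continue
        bounds = sorted({b for s in segs for b in (s.start, s.end)})
        atoms = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            dosage: dict[str, float] = {}
            for s in segs:
                if s.start <= lo and s.end >= hi:
                    d = _DOSAGE[s.state]
                    dosage[s.line] = max(dosage.get(s.line, 0.0), d)
            if dosage:
                atoms.append((lo, hi, dosage))
        # merge contiguous atoms with identical dosage vectors
        for lo, hi, dosage in atoms:
            if blocks and blocks[-1].chrom == chrom and blocks[-1].end == lo and blocks[-1].dosage == dosage:
                blocks[-1].end = hi
            else:
                blocks.append(Block(id="", chrom=chrom, start=lo, end=hi, dosage=dosage))
    for k, b in enumerate(blocks):
        b.id = f"block{k + 1}"
    return blocks


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def _design(X: np.ndarray, cols: list[int]) -> np.ndarray:
    n = X.shape[0]
    return np.column_stack([np.ones(n)] + [X[:, j] for j in cols])


def _partial_f_p(y: np.ndarray, X: np.ndarray, base: list[int], extra: int) -> float:
    """p-value for adding column ``extra`` to the model with ``base``."""
    n = len(y)
    rss0, _ = _rss(y, _design(X, base))
    rss1, _ = _rss(y, _design(X, base + [extra]))
    dfe = n - (len(base) + 2)
    if dfe <= 0 or rss1 <= 0:
        return 0.0
    f = max(rss0 - rss1, 0.0) / (rss1 / dfe)
    return float(stats.f.sf(f, 1, dfe))


def _drop_collinear(X: np.ndarray, ids: list[str]) -> list[int]:
    """Indices of columns to keep in the cofactor pool; later columns that
    are (numerically) linear combinations of earlier ones are dropped."""
    keep: list[int] = []
    n = X.shape[0]
    basis = np.ones((n, 1))
    for j in range(X.shape[1]):
        trial = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(trial) > basis.shape[1]:
            keep.append(j)
            basis = trial
        else:
            logger.info("block %s dropped from cofactor pool (collinear)", ids[j])
    return keep


def stepwise_select(
    y: np.ndarray, X: np.ndarray, pool: list[int], p_in: float, p_out: float, max_iter: int = 100
) -> list[int]:
    """Forward-backward stepwise selection over columns of X (by index)."""
    selected: list[int] = []
    for _ in range(max_iter):
        changed = False
        candidates = [j for j in pool if j not in selected]
        if candidates and len(selected) + 3 < len(y):
            pvals = [(_partial_f_p(y, X, selected, j), j) for j in candidates]
            p_best, j_best = min(pvals)
            if p_best <= p_in:
                selected.append(j_best)
                changed = True
        # backward elimination
        while len(selected) > 0:
            pvals = [
                (_partial_f_p(y, X, [k for k in selected if k != j], j), j) for j in selected
            ]
            p_worst, j_worst = max(pvals)
            if p_worst >= p_out:
                selected.remove(j_worst)
                changed = True
            else:
                break
        if not changed:
            break
    return selected


def scan_qtl(
    blocks: list[Block],
    blups: pd.DataFrame | pd.Series,
    params: QtlScanParams | None = None,
) -> pd.DataFrame:
    """Block-based stepwise likelihood-ratio QTL scan.

    ``blups`` is a Series (one trait, index = line) or a lines x traits
    DataFrame.  For each trait: (1) stepwise selection picks background
    cofactor blocks; (2) each block b is tested by contrasting the cofactor
    model without b against the one including b; (3) blocks with
    LOD >= ``lod_threshold`` are reported with PVE, additive effect, and a
    ``q-<TRAIT><CHR>[-k]`` name.
    """
    params = params or QtlScanParams()
    if isinstance(blups, pd.Series):
        blups = blups.to_frame(name=blups.name or "trait1")
    lines = list(blups.index)
    n = len(lines)

    X_all = np.column_stack([b.dosage_vector(lines) for b in blocks]) if blocks else np.empty((n, 0))
    usable = []
    for j, b in enumerate(blocks):
        if np.ptp(X_all[:, j]) == 0:
            logger.warning("block %s has constant dosage among phenotyped lines; skipped", b.id)
        else:
            usable.append(j)
    X = X_all[:, usable]
    used_blocks = [blocks[j] for j in usable]
    pool = _drop_collinear(X, [b.id for b in used_blocks])

    results = []
    for trait in blups.columns:
        y = blups[trait].to_numpy(dtype=float)
        if np.any(~np.isfinite(y)):
            raise ValueError(f"non-finite BLUPs for trait {trait}")
        tss = float(np.sum((y - y.mean()) ** 2))
        selected = stepwise_select(y, X, pool, params.p_in, params.p_out)
        for j in pool:
            cof = [k for k in selected if k != j]
            rss_red, _ = _rss(y, _design(X, cof))
            rss_full, beta = _rss(y, _design(X, cof + [j]))
            if rss_full <= np.finfo(float).eps * max(tss, 1.0):
                lod = params.lod_cap
            else:
                lod = min((n / 2.0) * np.log10(rss_red / rss_full), params.lod_cap)
            lod = max(lod, 0.0)
            if lod < params.lod_threshold:
                continue
            a = beta[-1] / 2.0  # coefficient on dosage x; genotypic value is 2a*x
            if not params.donor_positive:
                a = -a
            pve = 100.0 * max(rss_red - rss_full, 0.0) / tss if tss > 0 else 0.0
            b = used_blocks[j]
            results.append(
                {
                    "trait": trait,
                    "block": b.id,
                    "chrom": b.chrom,
                    "lod": round(float(lod), 2),
                    "pve_pct": round(float(min(pve, 100.0)), 2),
                    "additive_effect": round(float(a), 4),
                    "start": b.start,
                    "end": b.end,
                }
            )
    df = pd.DataFrame(
        results,
        columns=["trait", "block", "chrom", "lod", "pve_pct", "additive_effect", "start", "end"],
    )
    return _name_qtl(df)


def _name_qtl(df: pd.DataFrame) -> pd.DataFrame:
    """q-<TRAIT><CHR> names, with '-k' ordinal suffix when one trait has
    several QTL on the same chromosome (ordered by position)."""
    if df.empty:
        df["qtl"] = pd.Series(dtype=str)
        return df[["trait", "qtl", "block", "chrom", "lod", "pve_pct", "additive_effect", "start", "end"]]
    df = df.sort_values(["trait", "chrom", "start"], kind="mergesort").reset_index(drop=True)
    names = []
    for (trait, chrom), grp in df.groupby(["trait", "chrom"], sort=False):
        base = f"q-{str(trait).upper()}{chrom}"
        if len(grp) == 1:
            names.append((grp.index[0], base))
        else:
            for k, idx in enumerate(grp.index, start=1):
                names.append((idx, f"{base}-{k}"))
    name_s = pd.Series(dict(names))
    df["qtl"] = name_s
    return df[["trait", "qtl", "block", "chrom", "lod", "pve_pct", "additive_effect", "start", "end"]]


def blocks_to_frame(blocks: list[Block]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.chrom, b.start, b.end, b.id, len(b.dosage)) for b in blocks],
        columns=["chrom", "start", "end", "block", "n_carriers"],
    )


def carrier_matrix(blocks: list[Block], lines) -> pd.DataFrame:
    """Lines x blocks dosage matrix."""
    data = {b.id: b.dosage_vector(lines) for b in blocks}
    return pd.DataFrame(data, index=list(lines))
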