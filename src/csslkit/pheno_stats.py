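"""Multi-environment phenotype statistics: BLUPs, broad-sense heritability,
trait correlations, and the weighted additive-effect statistic (WAF).

The per-trait model is a one-way random-effects model with fixed
environments,

    y_ij = mu + env_j + g_i + e_ij,     g_i ~ N(0, s2_g), e_ij ~ N(0, s2_e),

fitted by REML.  For balanced data the REML solution coincides with the
two-way ANOVA method-of-moments estimator, which is used directly; for
unbalanced data the model is fitted with statsmodels MixedLM.  Line BLUPs
shrink the environment-adjusted line means toward the grand mean by
k_i = s2_g / (s2_g + s2_e / n_i).  Broad-sense heritability on a line-mean
basis is H2 = s2_g / (s2_g + s2_e / n_env).

WAF (weight mean of additive effects) aggregates per-block additive effects
across traits with weights r_t * H2_t, where r_t is the (positive)
correlation of trait t with the anchor trait:

    WAF_b = sum_t Add_bt * r_t * H2_t / sum_t r_t * H2_t
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class BlupResult:
    """Per-trait variance components, heritability, and line BLUPs."""

    blups: pd.DataFrame  # lines x traits
    var_g: dict[str, float] = field(default_factory=dict)
    var_e: dict[str, float] = field(default_factory=dict)
    h2: dict[str, float] = field(default_factory=dict)
    n_envs: dict[str, int] = field(default_factory=dict)

    def h2_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": list(self.h2),
                "var_g": [self.var_g[t] for t in self.h2],
                "var_e": [self.var_e[t] for t in self.h2],
                "n_envs": [self.n_envs[t] for t in self.h2],
                "H2": [self.h2[t] for t in self.h2],
            }
        )


def _is_balanced(pivot: pd.DataFrame) -> bool:
    return not pivot.isna().any().any()


def _fit_balanced(pivot: pd.DataFrame) -> tuple[float, float, pd.Series, float]:
    """Two-way (line + env, no interaction) ANOVA variance components;
    equals REML for balanced data.  Returns (var_g, var_e, adjusted line
    means, grand mean)."""
    y = pivot.to_numpy(dtype=float)
    n_lines, n_env = y.shape
    grand = y.mean()
    line_means = y.mean(axis=1)
    env_means = y.mean(axis=0)
    resid = y - line_means[:, None] - env_means[None, :] + grand
    df_e = (n_lines - 1) * (n_env - 1)
    var_e = float((resid**2).sum() / df_e) if df_e > 0 else 0.0
    ms_line = n_env * float(((line_means - grand) ** 2).sum() / (n_lines - 1))
    var_g = max(0.0, (ms_line - var_e) / n_env)
    adj_means = pd.Series(line_means, index=pivot.index)  # env effects cancel (balanced)
    return var_g, var_e, adj_means, float(grand)


def _fit_unbalanced(df: pd.DataFrame) -> tuple[float, float, pd.Series, float, pd.Series]:
    """REML fit via MixedLM for unbalanced line x env tables.  Returns
    (var_g, var_e, adjusted line means, grand mean, per-line n)."""
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ C(env)", data=df, groups=df["line"])
        fit = model.fit(reml=True, method="lbfgs")
    var_g = float(fit.cov_re.iloc[0, 0])
    var_e = float(fit.scale)
    # environment-adjusted observations, then line means
    env_eff = df.groupby("env")["value"].mean()
    env_eff = env_eff - env_eff.mean()
    adj = df["value"] - df["env"].map(env_eff)
    adj_means = adj.groupby(df["line"]).mean()
    grand = float(adj.mean())
    n_i = df.groupby("line")["value"].count()
    return var_g, var_e, adj_means, grand, n_i


def fit_blup(table: pd.DataFrame, h2_basis: str = "line-mean") -> BlupResult:
    """Fit the random-line model per trait and return BLUPs, variance
    components, and H2.

    ``table`` is long-format with columns (line, env, trait, value);
    replicate columns, if present, are pooled into the residual.  Traits
    observed in a single environment get H2 = NaN (warned) and unshrunken
    line means as BLUPs.  ``h2_basis``: 'line-mean' divides s2_e by the
    number of environments; 'plot' uses s2_e directly.
    """
    if h2_basis not in ("line-mean", "plot"):
        raise ValueError("h2_basis must be 'line-mean' or 'plot'")
    required = {"line", "env", "trait", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"phenotype table must have columns {sorted(required)}")
    if table["line"].nunique() < 2:
        raise ValueError("need at least 2 lines")

    res = BlupResult(blups=pd.DataFrame(index=sorted(table["line"].unique())))
    for trait, df in table.groupby("trait", sort=False):
        df = df.dropna(subset=["value"])
        n_env = df["env"].nunique()
        res.n_envs[trait] = int(n_env)
        if n_env < 2:
            logger.warning("trait %s observed in a single environment; H2 undefined", trait)
            means = df.groupby("line")["value"].mean()
            res.blups[trait] = means.reindex(res.blups.index)
            res.var_g[trait] = float("nan")
            res.var_e[trait] = float("nan")
            res.h2[trait] = float("nan")
            continue
        # pool replicates: average within line x env first
        cell = df.groupby(["line", "env"], sort=True)["value"].mean().reset_index()
        pivot = cell.pivot(index="line", columns="env", values="value")
        if _is_balanced(pivot):
            var_g, var_e, adj_means, grand = _fit_balanced(pivot)
            n_i = pd.Series(pivot.shape[1], index=pivot.index)
        else:
            var_g, var_e, adj_means, grand, n_i = _fit_unbalanced(cell)
        denom = var_g + (var_e / n_env if h2_basis == "line-mean" else var_e)
        res.var_g[trait] = var_g
        res.var_e[trait] = var_e
        res.h2[trait] = var_g / denom if denom > 0 else float("nan")
        if var_g + var_e <= 0:
            k = pd.Series(1.0, index=adj_means.index)
        else:
            k = var_g / (var_g + var_e / n_i.reindex(adj_means.index))
        blup = grand + k * (adj_means - grand)
        res.blups[trait] = blup.reindex(res.blups.index)
    return res


def trait_correlations(blups: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations over lines with two-tailed p-values and
    significance flags ('*' at 0.05, '**' at 0.01).

    Zero-variance traits get an NA row/column.
    """
    if len(blups) < 3:
        raise ValueError("need at least 3 lines for correlations")
    traits = list(blups.columns)
    r = pd.DataFrame(np.nan, index=traits, columns=traits)
    p = pd.DataFrame(np.nan, index=traits, columns=traits)
    flags = pd.DataFrame("", index=traits, columns=traits)
    for i, t1 in enumerate(traits):
        for t2 in traits[i:]:
            x = blups[t1].to_numpy(dtype=float)
            y = blups[t2].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            if t1 == t2:
                rr, pp = 1.0, 0.0
            else:
                rr, pp = stats.pearsonr(x[ok], y[ok])
            r.loc[t1, t2] = r.loc[t2, t1] = rr
            p.loc[t1, t2] = p.loc[t2, t1] = pp
            flag = "**" if pp < 0.01 else "*" if pp < 0.05 else ""
            flags.loc[t1, t2] = flags.loc[t2, t1] = flag
    return r, p, flags


def compute_waf(
    additive: pd.DataFrame,
    r: pd.Series | dict[str, float],
    h2: pd.Series | dict[str, float],
) -> pd.Series:
    """Weighted mean of per-trait additive effects per block.

    ``additive`` is blocks x traits (NaN where a trait has no estimate for
    a block); ``r`` maps trait -> positive correlation coefficient with the
    anchor trait and ``h2`` maps trait -> broad-sense heritability.  The
    weight of trait t is r_t * H2_t.  Blocks with no additive estimate at
    all yield NaN (warned).
    """
    r = pd.Series(r, dtype=float)
    h2 = pd.Series(h2, dtype=float)
    traits = [t for t in additive.columns if t in r.index and t in h2.index]
    if not traits:
        raise ValueError("no traits shared between additive matrix and weights")
    r = r[traits]
    h2 = h2[traits]
    if (r <= 0).any():
        bad = list(r.index[r <= 0])
        raise ValueError(f"correlation weights must be positive; offending traits: {bad}")
    w = r * h2
    if w.sum() <= 0:
        raise ValueError("all WAF weights are zero")
    A = additive[traits]
    num = (A * w).sum(axis=1, skipna=True)
    den = A.notna().mul(w, axis=1).sum(axis=1)
    waf = num / den.replace(0.0, np.nan)
    n_empty = int(waf.isna().sum())
    if n_empty:
        logger.warning("%d blocks have no additive estimates; WAF set to NA", n_empty)
    return waf


def waf_track(waf: pd.Series, blocks) -> pd.DataFrame:
    """Per-genome WAF track over block intervals (chrom, start, end, block,
    WAF), for chromosome-painting style exports."""
    rows = []
    by_id = {b.id: b for b in blocks}
    for block_id, value in waf.items():
        b = by_id[block_id]
        rows.append((b.chrom, b.start, b.end, block_id, value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "block", "waf"])
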