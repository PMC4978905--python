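"""Line-mean preparation, variance components, heritability and derived traits.

Replicated plot records are reduced to one adjusted mean per line (a BLUE from
the additive fixed model ``value ~ line + environment + replicate-within-
environment``); with balanced data this equals the per-line arithmetic mean.
Variance components come from the method of moments on the line x environment
ANOVA, and broad-sense heritability is on an entry-mean basis:

    H2 = s2_G / (s2_G + s2_GxE / E + s2_err / (E * R))

with E environments and R replicates per environment (harmonic mean when
replication differs between environments).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ID_COLS = ["line_id", "population", "environment", "replicate"]


def _trait_columns(plots: pd.DataFrame) -> list[str]:
    return [c for c in plots.columns if c not in ID_COLS]


def compute_line_means(plots: pd.DataFrame,
                       traits: list[str] | None = None) -> pd.DataFrame:
    """Adjusted line means (BLUEs) from plot-level data.

    Environment effects and replicate-within-environment effects are removed
    under sum-to-zero constraints so that line coefficients are directly
    interpretable as adjusted means on the original trait scale. Missing plot
    values are dropped listwise within trait. Lines observed in a single plot
    pass their value through with a warning.
    """
    traits = traits or _trait_columns(plots)
    lines = pd.unique(plots["line_id"])
    pops = plots.drop_duplicates("line_id").set_index("line_id")["population"]
    line_pos = pd.Series(np.arange(len(lines)), index=lines)
    out = pd.DataFrame({"line_id": lines, "population": pops[lines].to_numpy()})

    envs = pd.unique(plots["environment"])
    env_pos = pd.Series(np.arange(len(envs)), index=envs)
    reps_by_env = {
        e: pd.unique(plots.loc[plots["environment"] == e, "replicate"])
        for e in envs
    }

    for trait in traits:
        sub = plots[ID_COLS + [trait]].dropna(subset=[trait])
        counts = sub["line_id"].value_counts()
        single = counts[counts == 1]
        if len(single):
            warnings.warn(
                f"{trait}: {len(single)} line(s) observed in a single plot; "
                "mean passed through unadjusted for replication"
            )
        n = len(sub)
        li = line_pos[sub["line_id"]].to_numpy()
        ei = env_pos[sub["environment"]].to_numpy()

        ncol_env = max(len(envs) - 1, 0)
        rep_cols = []
        for e in envs:
            rs = reps_by_env[e]
            for r in rs[:-1]:
                rep_cols.append((e, r, rs[-1]))
        X = np.zeros((n, len(lines) + ncol_env + len(rep_cols)))
        X[np.arange(n), li] = 1.0
        # environment: sum-to-zero coding
        for j in range(ncol_env):
            col = len(lines) + j
            X[ei == j, col] = 1.0
            X[ei == len(envs) - 1, col] = -1.0
        # replicate within environment: sum-to-zero within each environment
        for j, (e, r, rlast) in enumerate(rep_cols):
            col = len(lines) + ncol_env + j
            in_e = sub["environment"].to_numpy() == e
            rep = sub["replicate"].to_numpy()
            X[in_e & (rep == r), col] = 1.0
            X[in_e & (rep == rlast), col] = -1.0
        beta, *_ = np.linalg.lstsq(X, sub[trait].to_numpy(float), rcond=None)
        vals = beta[: len(lines)]
        observed = np.isin(lines, sub["line_id"].unique())
        vals = np.where(observed, vals, np.nan)
        out[trait] = vals
    return out


@dataclass
class VarianceComponents:
    """Method-of-moments variance components per trait, with the E and R used
    for entry-mean heritability."""

    table: pd.DataFrame  # index: trait; cols sigma2_g, sigma2_ge, sigma2_err
    n_environments: int
    r_effective: float  # harmonic-mean replicates per environment
    flags: dict[str, list[str]]


def estimate_variance_components(plots: pd.DataFrame,
                                 traits: list[str] | None = None) -> VarianceComponents:
    """ANOVA method-of-moments components of the line x environment model.

    For balanced data (L lines x E environments x R replicates) this is the
    textbook expected-mean-squares solution:

        s2_err = MS_error
        s2_GE  = (MS_GE - MS_error) / R
        s2_G   = (MS_G - MS_GE) / (E * R)

    With environment-specific replication, s2_err is the pooled within-cell
    variance and the cell-mean ANOVA uses the harmonic-mean R. Negative
    moment estimates are truncated to 0 (flagged). With one environment the
    GxE component is undefined and reported as 0 (flagged).
    """
    traits = traits or _trait_columns(plots)
    envs = pd.unique(plots["environment"])
    E = len(envs)
    reps = [plots.loc[plots["environment"] == e, "replicate"].nunique() for e in envs]
    r_h = len(reps) / sum(1.0 / r for r in reps)

    rows, flags = [], {}
    for trait in traits:
        f: list[str] = []
        sub = plots[["line_id", "environment", trait]].dropna(subset=[trait])
        cells = sub.groupby(["line_id", "environment"])[trait]
        cell_mean = cells.mean().unstack()
        cell_n = cells.size().unstack()
        # pooled within-cell variance
        ss_within = ((sub[trait] - cells.transform("mean")) ** 2).sum()
        df_within = int((cell_n - 1).clip(lower=0).sum().sum())
        s2_err = ss_within / df_within if df_within > 0 else 0.0
        if df_within == 0:
            f.append("no within-cell replication; sigma2_err = 0")

        complete = cell_mean.dropna()
        L = len(complete)
        if E >= 2 and L >= 2:
            y = complete.to_numpy(float)
            line_m = y.mean(axis=1)
            env_m = y.mean(axis=0)
            grand = y.mean()
            ms_g_cell = E * np.sum((line_m - grand) ** 2) / (L - 1)
            inter = y - line_m[:, None] - env_m[None, :] + grand
            ms_ge_cell = np.sum(inter ** 2) / ((L - 1) * (E - 1))
            # E[ms_ge_cell] = s2_GE + s2_err / R~ ; E[ms_g_cell] = E*s2_G + s2_GE + s2_err/R~
            s2_ge = ms_ge_cell - s2_err / r_h
            s2_g = (ms_g_cell - ms_ge_cell) / E
        elif E == 1:
            f.append("single environment; sigma2_GE undefined, set to 0")
            s2_ge = 0.0
            y = complete.to_numpy(float).ravel()
            s2_g = float(np.var(y, ddof=1)) - s2_err / r_h if len(y) > 1 else 0.0
        else:
            s2_ge = s2_g = 0.0
            f.append("fewer than 2 complete lines; components set to 0")
        if s2_ge < 0:
            f.append("sigma2_GE truncated to 0")
            s2_ge = 0.0
        if s2_g < 0:
            f.append("sigma2_G truncated to 0")
            s2_g = 0.0
        rows.append((trait, float(s2_g), float(s2_ge), float(s2_err)))
        flags[trait] = f
        for msg in f:
            logger.info("%s: %s", trait, msg)
    table = pd.DataFrame(
        rows, columns=["trait", "sigma2_g", "sigma2_ge", "sigma2_err"]
    ).set_index("trait")
    return VarianceComponents(table, E, r_h, flags)


def heritability(vc: VarianceComponents) -> pd.Series:
    """Entry-mean broad-sense heritability per trait, in [0, 1]; NaN when all
    components are zero."""
    t = vc.table
    denom = t["sigma2_g"] + t["sigma2_ge"] / vc.n_environments \
        + t["sigma2_err"] / (vc.n_environments * vc.r_effective)
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = t["sigma2_g"] / denom
    h2[denom <= 0] = np.nan
    return h2.clip(0.0, 1.0).rename("H2")


def derive_traits(means: pd.DataFrame) -> pd.DataFrame:
    """Append factor form density (FFD) and length/width ratio (L/W).

    FFD = mean single-kernel weight (mg) / kernel projected area (mm^2)
        = (Wt50k / 50 * 1000) / area   [mg/mm^2]
    LW  = length / width               [unitless]

    Lines with zero area or width get a missing value (logged).
    """
    out = means.copy()
    if {"Wt50k", "area"} <= set(out.columns):
        area = out["area"].to_numpy(float)
        bad = area == 0
        if bad.any():
            logger.warning("FFD: %d line(s) with zero area set missing", bad.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            ffd = (out["Wt50k"].to_numpy(float) / 50.0 * 1000.0) / area
        ffd[bad] = np.nan
        out["FFD"] = ffd
    if {"length", "width"} <= set(out.columns):
        width = out["width"].to_numpy(float)
        bad = width == 0
        if bad.any():
            logger.warning("L/W: %d line(s) with zero width set missing", bad.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            lw = out["length"].to_numpy(float) / width
        lw[bad] = np.nan
        out["LW"] = lw
    return out


def trait_framework(means: pd.DataFrame,
                    traits: list[str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Descriptive statistics and the Pearson correlation framework.

    Returns (descriptives, r matrix, p matrix). Stars for the usual display:
    '*' at p < 0.05, '**' at p < 0.001; constant traits give missing
    correlations.
    """
    traits = traits or [c for c in means.columns if c not in ("line_id", "population")]
    if len(means) < 3:
        raise ValueError("need at least 3 lines for the trait framework")
    desc_rows = []
    for t in traits:
        v = means[t].dropna().to_numpy(float)
        desc_rows.append((t, len(v), v.mean(), v.std(ddof=1), v.min(), v.max()))
    desc = pd.DataFrame(desc_rows, columns=["trait", "n", "mean", "sd", "min", "max"])

    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            pair = means[[traits[i], traits[j]]].dropna()
            x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
            if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rmat = pd.DataFrame(r, index=traits, columns=traits)
    pmat = pd.DataFrame(p, index=traits, columns=traits)
    return desc, rmat, pmat


def correlation_stars(rmat: pd.DataFrame, pmat: pd.DataFrame) -> pd.DataFrame:
    """Display table: r to 3 dp with significance stars."""
    def fmt(r, p):
        if np.isnan(r):
            return ""
        star = "**" if p < 0.001 else ("*" if p < 0.05 else "")
        return f"{r:.3f}{star}"
    return pd.DataFrame(
        [[fmt(rmat.iat[i, j], pmat.iat[i, j]) for j in range(rmat.shape[1])]
         for i in range(rmat.shape[0])],
        index=rmat.index, columns=rmat.columns,
    )
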