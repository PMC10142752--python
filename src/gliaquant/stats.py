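"""Cohort statistics: Mann-Whitney group comparisons under two-stage
Benjamini-Krieger-Yekutieli FDR control, Spearman correlation matrices, and
the longitudinal two-way ANOVA with Bonferroni-adjusted per-timepoint
contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "mann_whitney_u",
    "bky_two_stage_adjust",
    "compare_groups",
    "CorrelationMatrix",
    "spearman_matrix",
    "two_way_anova_bonferroni",
    "significance_stars",
]

#: Combined-sample-size boundary between the exact and the normal-
#: approximation Mann-Whitney p-value.
EXACT_N_MAX = 16


def significance_stars(p: float) -> str:
    for cut, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p <= cut:
            return mark
    return "ns"


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U for x, p).

    Exact enumeration p when the combined sample is small (n_x + n_y <=
    16) and tie-free; tie-corrected normal approximation with continuity
    correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= EXACT_N_MAX and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _bh_reject(p_sorted: np.ndarray, alpha: float) -> int:
    """Number of rejections of the linear (BH) step-up at level alpha on an
    ascending p-value array."""
    m = p_sorted.size
    crit = alpha * np.arange(1, m + 1) / m
    below = np.nonzero(p_sorted <= crit)[0]
    return int(below[-1] + 1) if below.size else 0


def bky_two_stage_adjust(pvals: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Two-stage linear step-up FDR control (Benjamini, Krieger &
    Yekutieli, adaptive). Returns boolean discovery flags.

    Stage 1 runs the linear step-up at q' = q/(1+q); its rejection count r1
    estimates the number of true nulls m0 = m - r1. If r1 = 0 nothing is
    discovered; if r1 = m everything is. Otherwise stage 2 reruns the
    linear step-up at level q'* m / m0.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1D array")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    q1 = q / (1.0 + q)
    r1 = _bh_reject(p_sorted, q1)
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    m0 = m - r1
    r2 = _bh_reject(p_sorted, q1 * m / m0)
    flags = np.zeros(m, dtype=bool)
    flags[order[:r2]] = True
    return flags


def compare_groups(
    endpoints: pd.DataFrame,
    q: float = 0.01,
    group_col: str = "group",
    groups: tuple[str, str] = ("control", "disease"),
) -> pd.DataFrame:
    """Control-vs-disease Mann-Whitney tests per endpoint, adjusted per
    region with the two-stage BKY procedure at FDR ``q``.

    ``endpoints`` is long format with columns (case_id, group, region,
    endpoint, value); the family adjusted together is all endpoints within
    one region (one figure-panel family). Returns one row per (region,
    endpoint) with group medians and n, U, raw p, the BKY discovery flag,
    and raw-p significance stars.
    """
    need = {"case_id", group_col, "region", "endpoint", "value"}
    if not need.issubset(endpoints.columns):
        raise ValueError(f"endpoints table needs columns {sorted(need)}")
    present = set(endpoints[group_col].unique())
    if len(present & set(groups)) < 2:
        raise ValueError(f"need both groups {groups}, found {sorted(present)}")
    rows = []
    for region, fam in endpoints.groupby("region", sort=True, observed=True):
        fam_rows = []
        for endpoint, sub in fam.groupby("endpoint", sort=True, observed=True):
            a = sub.loc[sub[group_col] == groups[0], "value"].dropna().to_numpy()
            b = sub.loc[sub[group_col] == groups[1], "value"].dropna().to_numpy()
            if min(a.size, b.size) < 3:
                warnings.warn(
                    f"{region}/{endpoint}: fewer than 3 cases in a group"
                )
            u, p = mann_whitney_u(a, b)
            fam_rows.append(
                {
                    "region": region,
                    "endpoint": endpoint,
                    f"median_{groups[0]}": float(np.median(a)),
                    f"median_{groups[1]}": float(np.median(b)),
                    f"n_{groups[0]}": a.size,
                    f"n_{groups[1]}": b.size,
                    "U": u,
                    "p_raw": p,
                }
            )
        flags = bky_two_stage_adjust(
            np.array([r["p_raw"] for r in fam_rows]), q=q
        )
        for r, f in zip(fam_rows, flags):
            r["bky_discovery"] = bool(f)
            r["stars_raw_p"] = significance_stars(r["p_raw"])
        rows.extend(fam_rows)
    return pd.DataFrame(rows)


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman correlation matrix with p-values and strength
    flags (|r| > 0.7 is labelled "very strong")."""

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    very_strong: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1 :]:
                rows.append(
                    {
                        "var_a": a,
                        "var_b": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "very_strong": bool(self.very_strong.loc[a, b])
                        if np.isfinite(self.r.loc[a, b])
                        else False,
                    }
                )
        return pd.DataFrame(rows)


def spearman_matrix(
    variables: pd.DataFrame,
    suppress: tuple[str, ...] = (),
    min_n: int = 4,
) -> CorrelationMatrix:
    """Pairwise Spearman correlations over a per-case variable table.

    Pairwise-complete observations; tie-corrected r with two-sided p.
    Constant variables yield null (NaN) correlations with a warning. Pairs
    involving a ``suppress``-listed variable are nulled — used to skip
    pTDP-43 correlations in control cases, which carry no aggregates.
    """
    cols = list(variables.columns)
    m = len(cols)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(m):
        for j in range(i + 1, m):
            if cols[i] in suppress or cols[j] in suppress:
                continue
            pair = variables[[cols[i], cols[j]]].dropna()
            if len(pair) < min_n:
                warnings.warn(
                    f"{cols[i]} vs {cols[j]}: only {len(pair)} complete pairs"
                )
                continue
            a = pair[cols[i]].to_numpy()
            b = pair[cols[j]].to_numpy()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                warnings.warn(f"constant variable in pair {cols[i]} vs {cols[j]}")
                continue
            res = sps.spearmanr(a, b)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    strong = (r_df.abs() > 0.7) & ~np.eye(m, dtype=bool)
    return CorrelationMatrix(cols, r_df, p_df, strong)


def two_way_anova_bonferroni(
    data: pd.DataFrame,
    value: str,
    factor_a: str = "genotype",
    factor_b: str = "timepoint",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA (Type-III sums of squares, unbalanced cells allowed)
    with Bonferroni-adjusted between-genotype contrasts at each timepoint.

    Contrasts use the pooled residual variance from the full model; the
    raw contrast p is multiplied by the number of timepoints and capped at
    1. Returns (anova_table, contrasts_table). A factor cell with zero
    observations is an error naming the cell.
    """
    for fa in (factor_a, factor_b):
        if data[fa].nunique() < 2:
            raise ValueError(f"factor {fa!r} needs >= 2 levels")
    counts = data.groupby([factor_a, factor_b], observed=True)[value].count()
    full = pd.MultiIndex.from_product(
        [data[factor_a].unique(), data[factor_b].unique()]
    )
    empty = [c for c in full if c not in counts.index or counts[c] == 0]
    if empty:
        raise ValueError(f"empty design cell(s): {empty}")

    df = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a, Sum) * C(_b, Sum)", data=df).fit()
    table = anova_lm(model, typ=3).rename(
        index={
            "C(_a, Sum)": factor_a,
            "C(_b, Sum)": factor_b,
            "C(_a, Sum):C(_b, Sum)": f"{factor_a}:{factor_b}",
        }
    )
    table = table.drop(index="Intercept", errors="ignore")

    mse = model.mse_resid
    dfr = model.df_resid
    levels_a = sorted(data[factor_a].unique())
    timepoints = sorted(data[factor_b].unique())
    n_t = len(timepoints)
    rows = []
    for t in timepoints:
        sub = data[data[factor_b] == t]
        for i, g1 in enumerate(levels_a):
            for g2 in levels_a[i + 1 :]:
                v1 = sub.loc[sub[factor_a] == g1, value].to_numpy()
                v2 = sub.loc[sub[factor_a] == g2, value].to_numpy()
                se = np.sqrt(mse * (1 / v1.size + 1 / v2.size))
                tval = (v1.mean() - v2.mean()) / se
                p_raw = 2 * sps.t.sf(abs(tval), dfr)
                rows.append(
                    {
                        factor_b: t,
                        "contrast": f"{g1} - {g2}",
                        "diff": v1.mean() - v2.mean(),
                        "t": tval,
                        "p_raw": p_raw,
                        "p_bonferroni": min(p_raw * n_t, 1.0),
                        "stars": significance_stars(min(p_raw * n_t, 1.0)),
                    }
                )
    return table, pd.DataFrame(rows)
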