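"""Study statistics: two-way ANOVA + Sidak, one-way ANOVA + Tukey, Pearson r.

Group comparisons follow the study's conventions: two-way ANOVA with two
between-subject factors (e.g. APOE isoform and Trem2 status) followed by
Sidak-adjusted pairwise comparisons, one-way ANOVA followed by Tukey's HSD
(studentized-range) test, Pearson correlation with the t-transform p-value,
and group summaries as mean ± SEM (sd/√n).

Degenerate designs follow fixed conventions: a zero between-group sum of
squares gives F = 0 and p = 1 even when the residual variance is also zero;
a zero residual variance with a real effect gives F = ∞ and p = 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "two_way_anova",
    "one_way_anova_tukey",
    "sidak_adjust",
    "pearson_r",
    "group_summary",
]


@dataclass
class AnovaResult:
    """ANOVA effects, pairwise comparisons, and group summaries."""

    effects: pd.DataFrame  # index: term; columns: ss, df, F, p
    pairwise: pd.DataFrame  # per-comparison raw and adjusted p
    group_stats: pd.DataFrame  # mean, sem, n per group/cell
    residual_df: float
    mse: float
    family_size: int | None = None  # m used for the Sidak adjustment
    method: str = ""


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Sidak family-wise adjustment ``1 − (1 − p)^m``."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return 1.0 - (1.0 - np.asarray(p, float)) ** m if np.ndim(p) else float(1.0 - (1.0 - p) ** m)


def _f_p(ss_eff: float, df_eff: float, ss_res: float, df_res: float) -> tuple[float, float]:
    """F and p with the degenerate-variance conventions."""
    if df_res <= 0:
        return np.nan, np.nan
    ms_res = ss_res / df_res
    ms_eff = ss_eff / df_eff
    if ss_eff <= 1e-12 * max(1.0, abs(ss_res)):
        return 0.0, 1.0
    if ms_res == 0 or ms_res <= 1e-12 * ms_eff:
        return np.inf, 0.0
    F = ms_eff / ms_res
    return float(F), float(stats.f.sf(F, df_eff, df_res))


def _cell_means_design(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Full-rank sum-to-zero (effects) coding for a two-factor model."""
    a_levels = sorted(a.unique())
    b_levels = sorted(b.unique())
    cols: list[np.ndarray] = [np.ones(len(a))]
    names = ["intercept"]

    def _code(series: pd.Series, levels: list[str], tag: str) -> list[np.ndarray]:
        out = []
        last = levels[-1]
        for lev in levels[:-1]:
            v = np.where(series == lev, 1.0, np.where(series == last, -1.0, 0.0))
            out.append(v)
            names.append(f"{tag}[{lev}]")
        return out

    a_cols = _code(a, a_levels, "A")
    cols += a_cols
    b_cols = _code(b, b_levels, "B")
    cols += b_cols
    for (ia, av), (ib, bv) in itertools.product(enumerate(a_cols), enumerate(b_cols)):
        cols.append(av * bv)
        names.append(f"A{ia}:B{ib}")
    return np.column_stack(cols), names


def _type3_ss(y: np.ndarray, X: np.ndarray, names: list[str], term_prefixes: dict[str, list[int]]) -> dict[str, float]:
    """Type III sums of squares: SSE increase when a term's columns are dropped."""

    def _sse(M: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        resid = y - M @ beta
        return float(resid @ resid)

    sse_full = _sse(X)
    out = {"__residual__": sse_full}
    for term, idx in term_prefixes.items():
        keep = [i for i in range(X.shape[1]) if i not in idx]
        out[term] = _sse(X[:, keep]) - sse_full
    return out


def two_way_anova(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    pairwise_family: str = "within",
) -> AnovaResult:
    """Two-way between-subject ANOVA with Sidak pairwise comparisons.

    Uses Type III sums of squares with sum-to-zero coding (the convention of
    the common GraphPad-style analysis of unbalanced designs).  Pairwise
    comparisons use the pooled residual variance;
    ``pairwise_family="within"`` compares the levels of each factor within
    each level of the other (each direction forming one Sidak family);
    ``"cells"`` compares all cell pairs in one family.

    Requires ≥2 levels per factor and every cell occupied.
    """
    d = data[[value, factor_a, factor_b]].dropna()
    a, b, y = d[factor_a].astype(str), d[factor_b].astype(str), d[value].to_numpy(float)
    a_levels, b_levels = sorted(a.unique()), sorted(b.unique())
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("each factor needs at least 2 levels")
    cells = d.groupby([factor_a, factor_b], observed=True)[value]
    counts = cells.count()
    for la in a_levels:
        for lb in b_levels:
            if (la, lb) not in counts.index or counts[(la, lb)] == 0:
                raise ValueError(f"empty cell: ({factor_a}={la}, {factor_b}={lb})")
    X, names = _cell_means_design(a, b)
    n_a, n_b = len(a_levels) - 1, len(b_levels) - 1
    idx_a = list(range(1, 1 + n_a))
    idx_b = list(range(1 + n_a, 1 + n_a + n_b))
    idx_ab = list(range(1 + n_a + n_b, X.shape[1]))
    ss = _type3_ss(y, X, names, {factor_a: idx_a, factor_b: idx_b, "interaction": idx_ab})
    df_res = len(y) - X.shape[1]
    rows = []
    for term, df_eff in ((factor_a, n_a), (factor_b, n_b), ("interaction", n_a * n_b)):
        F, p = _f_p(ss[term], df_eff, ss["__residual__"], df_res)
        rows.append({"term": term, "ss": ss[term], "df": df_eff, "F": F, "p": p})
    effects = pd.DataFrame(rows).set_index("term")
    mse = ss["__residual__"] / df_res if df_res > 0 else np.nan

    cell_stats = cells.agg(["mean", "count", "std"]).rename(columns={"count": "n"})
    cell_stats["sem"] = cell_stats["std"] / np.sqrt(cell_stats["n"])

    comparisons = []
    if pairwise_family == "within":
        fams = []
        for la in a_levels:  # compare B levels within each A level
            for l1, l2 in itertools.combinations(b_levels, 2):
                fams.append((f"{factor_b} within {factor_a}", (la, l1), (la, l2)))
        for lb in b_levels:  # compare A levels within each B level
            for l1, l2 in itertools.combinations(a_levels, 2):
                fams.append((f"{factor_a} within {factor_b}", (l1, lb), (l2, lb)))
    elif pairwise_family == "cells":
        all_cells = list(itertools.product(a_levels, b_levels))
        fams = [("cells", c1, c2) for c1, c2 in itertools.combinations(all_cells, 2)]
    else:
        raise ValueError("pairwise_family must be 'within' or 'cells'")
    family_sizes = pd.Series([f for f, *_ in fams]).value_counts().to_dict()
    for fam, c1, c2 in fams:
        m1, n1 = cell_stats.loc[c1, "mean"], cell_stats.loc[c1, "n"]
        m2, n2 = cell_stats.loc[c2, "mean"], cell_stats.loc[c2, "n"]
        diff = m1 - m2
        se = np.sqrt(mse * (1.0 / n1 + 1.0 / n2)) if mse > 0 else 0.0
        if se == 0:
            p_raw = 1.0 if diff == 0 else 0.0
            t = 0.0 if diff == 0 else np.inf
        else:
            t = diff / se
            p_raw = float(2 * stats.t.sf(abs(t), df_res))
        m = family_sizes[fam]
        comparisons.append(
            {
                "family": fam, "group1": "/".join(c1), "group2": "/".join(c2),
                "diff": diff, "t": t, "p_raw": p_raw,
                "p_adj": sidak_adjust(p_raw, m), "m": m,
            }
        )
    pairwise = pd.DataFrame(comparisons)
    return AnovaResult(
        effects=effects,
        pairwise=pairwise,
        group_stats=cell_stats[["mean", "sem", "n"]],
        residual_df=df_res,
        mse=float(mse),
        family_size=None if pairwise_family == "within" else len(fams),
        method="two-way ANOVA (Type III) + Sidak",
    )


def one_way_anova_tukey(values: np.ndarray, groups: np.ndarray) -> AnovaResult:
    """One-way ANOVA with Tukey's HSD pairwise test.

    Adjusted p-values come from the studentized-range distribution with the
    Tukey-Kramer standard error for unequal group sizes.  Every group needs
    at least 2 observations.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    by = {g: values[groups == g] for g in levels}
    for g, v in by.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    n = len(values)
    k = len(levels)
    grand = values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in by.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by.values())
    df_b, df_w = k - 1, n - k
    F, p = _f_p(ss_between, df_b, ss_within, df_w)
    effects = pd.DataFrame(
        [{"term": "group", "ss": ss_between, "df": df_b, "F": F, "p": p}]
    ).set_index("term")
    mse = ss_within / df_w
    rows = []
    for g1, g2 in itertools.combinations(levels, 2):
        v1, v2 = by[g1], by[g2]
        diff = v1.mean() - v2.mean()
        se = np.sqrt(mse / 2 * (1 / len(v1) + 1 / len(v2)))
        if se == 0:
            p_adj = 1.0 if diff == 0 else 0.0
            q = 0.0 if diff == 0 else np.inf
        else:
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_w))
        rows.append({"group1": g1, "group2": g2, "diff": diff, "q": q, "p_adj": p_adj})
    stats_df = pd.DataFrame(
        {
            "mean": {g: v.mean() for g, v in by.items()},
            "sem": {g: v.std(ddof=1) / np.sqrt(len(v)) for g, v in by.items()},
            "n": {g: len(v) for g, v in by.items()},
        }
    )
    return AnovaResult(
        effects=effects,
        pairwise=pd.DataFrame(rows),
        group_stats=stats_df,
        residual_df=df_w,
        mse=float(mse),
        method="one-way ANOVA + Tukey HSD",
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Pearson r, R² and the two-sided t-transform p-value.

    Returns missing values when either input has zero variance; requires
    n ≥ 3.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r needs two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": np.nan, "r_squared": np.nan, "p": np.nan, "n": len(x)}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "r_squared": float(r**2), "p": float(p), "n": len(x)}


def group_summary(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Mean ± SEM (sd/√n) and n per group."""
    df = pd.DataFrame({"value": np.asarray(values, float), "group": np.asarray(groups)})
    g = df.groupby("group")["value"]
    out = g.agg(mean="mean", n="count")
    out["sem"] = g.std(ddof=1) / np.sqrt(out["n"])
    return out
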