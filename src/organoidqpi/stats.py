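"""Group comparisons: Welch's t-test, the two-sample variance F-test, and
longitudinal per-week summaries of a cohort feature table.

Both tests report two-tailed p-values; the F-test uses the standard
symmetric convention p = 2·min(CDF_F(F), 1 − CDF_F(F)) with the F CDF given
by the regularized incomplete beta function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "welch_t_test",
    "variance_f_test",
    "longitudinal_compare",
    "benjamini_hochberg",
]

log = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    """Result of one two-group test."""

    test: str
    statistic: float
    df: float | tuple[float, float]
    p_two_tailed: float
    n1: int
    n2: int
    flag: str | None = None


def welch_t_test(x, y) -> GroupComparison:
    """Two-tailed unpaired t-test with Welch correction.

    Degenerate zero-variance inputs are handled explicitly: equal means give
    t = 0, p = 1; unequal means give p = 0 with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if x.mean() == y.mean():
            return GroupComparison("welch_t", 0.0, float(min(n1, n2) - 1), 1.0, n1, n2)
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return GroupComparison(
            "welch_t", sign * np.inf, float(min(n1, n2) - 1), 0.0, n1, n2,
            flag="zero-variance groups with unequal means",
        )
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    denom = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    if denom > 0:
        df = se2**2 / denom
    else:
        # numerical underflow: one variance dominates completely, and the
        # Satterthwaite df tends to that sample's df in the limit
        df = float((n1 - 1) if v1 / n1 >= v2 / n2 else (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparison("welch_t", float(t), float(df), float(p), n1, n2)


def variance_f_test(x, y) -> GroupComparison:
    """Two-tailed F-test for equality of variances, F = s₁²/s₂²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v2 == 0:
        raise ZeroDivisionError("denominator group has zero variance")
    f = v1 / v2
    d1, d2 = n1 - 1, n2 - 1
    cdf = sps.f.cdf(f, d1, d2)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return GroupComparison("variance_f", float(f), (d1, d2), float(min(p, 1.0)), n1, n2)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; off by default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def longitudinal_compare(
    table: pd.DataFrame,
    feature_cols,
    group_col: str = "group",
    week_col: str = "week",
    unit_col: str = "organoid_id",
    switch_week: int | None = None,
    min_per_group: int = 2,
) -> dict:
    """Per-week two-group comparisons plus pre/post-switch summaries.

    The table is first aggregated to one value per observational unit
    (organoid) per week per feature (mean over tiles), then each week gets a
    Welch-t and a variance-F comparison per feature.  Weeks with fewer than
    ``min_per_group`` units in either group are skipped with a log entry.

    Returns ``{"per_week": DataFrame, "pre_post": DataFrame}``.
    """
    feature_cols = list(feature_cols)
    agg = (
        table.groupby([group_col, week_col, unit_col])[feature_cols]
        .mean()
        .reset_index()
    )
    groups = sorted(agg[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected two groups, found {groups}")
    g1, g2 = groups

    rows = []
    for week in sorted(agg[week_col].unique()):
        sub = agg[agg[week_col] == week]
        a = sub[sub[group_col] == g1]
        b = sub[sub[group_col] == g2]
        if len(a) < min_per_group or len(b) < min_per_group:
            log.info("week %s skipped: group sizes %d vs %d", week, len(a), len(b))
            continue
        for feat in feature_cols:
            xa, xb = a[feat].to_numpy(), b[feat].to_numpy()
            try:
                wt = welch_t_test(xa, xb)
                ft = variance_f_test(xa, xb)
            except (ValueError, ZeroDivisionError) as err:
                log.info("week %s feature %s skipped: %s", week, feat, err)
                continue
            rows.append(
                {
                    "week": week,
                    "feature": feat,
                    "mean_" + str(g1): xa.mean(),
                    "mean_" + str(g2): xb.mean(),
                    "t_stat": wt.statistic,
                    "t_df": wt.df,
                    "t_p": wt.p_two_tailed,
                    "f_stat": ft.statistic,
                    "f_df1": ft.df[0],
                    "f_df2": ft.df[1],
                    "f_p": ft.p_two_tailed,
                }
            )
    per_week = pd.DataFrame(rows)

    pre_rows = []
    if switch_week is not None:
        phase = np.where(agg[week_col] > switch_week, "post", "pre")
        agg2 = agg.assign(phase=phase)
        for (grp, ph), sub in agg2.groupby([group_col, "phase"]):
            for feat in feature_cols:
                pre_rows.append(
                    {
                        "group": grp,
                        "phase": ph,
                        "feature": feat,
                        "mean": sub[feat].mean(),
                        "sd": sub[feat].std(),
                        "n": len(sub),
                    }
                )
    return {"per_week": per_week, "pre_post": pd.DataFrame(pre_rows)}
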