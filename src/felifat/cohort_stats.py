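"""Cohort-level statistics: correlation/regression with automatic
natural-log transform, muscle-grade filtering, and rank-based group
comparison (Kruskal-Wallis with Dunn pairwise post-hoc tests).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cutoffs import RegressionFit


@dataclass(frozen=True)
class GroupComparison:
    statistic: float  # Kruskal-Wallis H, tie-corrected
    p: float
    pairwise: list[tuple[str, str, float]]  # (group_a, group_b, adjusted p)
    dropped: list[str]  # groups below the size floor


def correlate(
    table: pd.DataFrame,
    x: str,
    y: str,
    transform_policy: str = "auto",
    alpha: float = 0.05,
) -> RegressionFit:
    """OLS of y on x with Pearson r and a natural-log fallback.

    transform_policy:
      "none" — fit on the raw scales.
      "ln"   — natural log of both variables (requires positive values).
      "auto" — fit raw first; if a Shapiro-Wilk test rejects normality of
               the residuals at ``alpha`` and both variables are strictly
               positive, refit on ln-ln and record the transform used.
    """
    if transform_policy not in ("auto", "none", "ln"):
        raise ValueError(f"unknown transform_policy {transform_policy!r}")
    sub = table[[x, y]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 paired non-missing values")
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)

    def _fit(xa: np.ndarray, ya: np.ndarray, transform: str) -> RegressionFit:
        model = sm.OLS(ya, sm.add_constant(xa)).fit()
        r, p = sps.pearsonr(xa, ya)
        return RegressionFit(
            intercept=float(model.params[0]),
            slope=float(model.params[1]),
            r=float(r),
            r2=float(r) ** 2,
            p=float(p),
            transform=transform,
        )

    if transform_policy == "ln":
        if (xv <= 0).any() or (yv <= 0).any():
            raise ValueError("ln transform requires strictly positive values")
        return _fit(np.log(xv), np.log(yv), "ln_ln")

    raw = _fit(xv, yv, "none")
    if transform_policy == "none":
        return raw
    resid = yv - (raw.intercept + raw.slope * xv)
    _, shapiro_p = sps.shapiro(resid)
    if shapiro_p < alpha and (xv > 0).all() and (yv > 0).all():
        return _fit(np.log(xv), np.log(yv), "ln_ln")
    return raw


def filter_by_muscle(
    table: pd.DataFrame,
    exclude: tuple[str, ...] = ("atrophic", "hypertrophic"),
) -> tuple[pd.DataFrame, int]:
    """Drop rows with excluded muscle grades; returns (table, n_removed)."""
    if "muscle_grade" not in table.columns:
        raise ValueError("table lacks a muscle_grade column")
    keep = ~table["muscle_grade"].isin(exclude)
    return table[keep].reset_index(drop=True), int((~keep).sum())


def _dunn_pairwise(
    groups: dict[str, np.ndarray],
) -> list[tuple[str, str, float]]:
    """Dunn z-tests on pooled ranks with tie correction and Bonferroni
    family adjustment across all retained pairs."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks = {}
    start = 0
    for g in names:
        n_g = len(groups[g])
        mean_ranks[g] = ranks[start : start + n_g].mean()
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = math.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            if se == 0:
                p_adj = 1.0
            else:
                z = abs(mean_ranks[a] - mean_ranks[b]) / se
                p_adj = min(1.0, 2.0 * sps.norm.sf(z) * m)
            out.append((a, b, p_adj))
    return out


def compare_fc_groups(
    table: pd.DataFrame,
    value: str,
    groups: list[str],
    group_col: str = "visual_fc",
    min_group_size: int = 4,
) -> GroupComparison:
    """ANOVA on ranks (Kruskal-Wallis) with Dunn pairwise comparisons.

    Groups smaller than ``min_group_size`` are dropped with a warning
    (categories too sparse to rank reliably); at least two groups must
    remain.
    """
    samples: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for g in groups:
        vals = table.loc[table[group_col] == g, value].dropna().to_numpy(float)
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        if len(vals) < min_group_size:
            warnings.warn(
                f"dropping group {g!r} with n={len(vals)} < {min_group_size}",
                stacklevel=2,
            )
            dropped.append(g)
        else:
            samples[g] = vals
    if len(samples) < 2:
        raise ValueError("fewer than two groups retained for comparison")
    pooled = np.concatenate(list(samples.values()))
    if np.unique(pooled).size == 1:
        # scipy raises on all-identical data; H is 0 by definition there
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples.values())
    return GroupComparison(
        statistic=float(h),
        p=float(p),
        pairwise=_dunn_pairwise(samples),
        dropped=dropped,
    )
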