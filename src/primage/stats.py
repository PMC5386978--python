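"""Group statistics for volume trajectories and BrainAGE contrasts.

Covers the analysis layer of the study: per-sex volume-vs-age regressions
with linear/quadratic model comparison, two-group ANOVA recomputed from
summary statistics (mean, SD, n - the form in which published cohort tables
arrive), age-adjusted ANCOVA with partial eta-squared effect sizes, and the
MNR-vs-CTR BrainAGE group difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TrajectoryFit",
    "GroupComparison",
    "fit_trajectory",
    "anova_from_summary",
    "ancova_group",
    "brainage_group_difference",
]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group for one measured variable."""

    n: int
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class TrajectoryFit:
    """One polynomial age model for one volume response."""

    response: str
    order: int
    coefficients: np.ndarray     # ascending powers: intercept, age, age^2
    adjusted_r2: float
    f_stat: float
    p_value: float
    selected: bool = False

    def __post_init__(self):
        if self.adjusted_r2 > 1 + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed 1")
        if self.f_stat < 0:
            raise ValueError("F must be >= 0")
        if not (0 < self.p_value <= 1):
            raise ValueError("p must lie in (0, 1]")


@dataclass
class GroupComparison:
    """A one-factor group test: F, degrees of freedom, p, partial eta^2."""

    factor: str
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    partial_eta2: float
    covariates: tuple = ()

    def __post_init__(self):
        if np.isfinite(self.f_stat) and self.f_stat < 0:
            raise ValueError("F must be >= 0")
        if not (0 <= self.partial_eta2 <= 1):
            raise ValueError("partial eta^2 must lie in [0, 1]")
        if self.df_num < 1 or self.df_den < 1:
            raise ValueError("degrees of freedom must be positive integers")


def fit_trajectory(ages, values, orders=(1, 2), response: str = "volume",
                   alpha: float = 0.05, rule: str = "adjusted_r2"):
    """OLS polynomial fits of a volume against age, with order selection.

    For each order an ordinary least squares model ``value ~ age + ... +
    age^order`` is fitted; the overall F statistic, its p-value and the
    adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1) are recorded.

    Selection rules
    ---------------
    ``"adjusted_r2"`` (default): among orders whose overall F is significant
    at ``alpha``, pick the highest adjusted R^2 (ties -> lower order).
    ``"nested_f"``: pick the quadratic iff its quadratic term is significant
    at ``alpha`` in the nested comparison, else the linear model.

    Returns a dict mapping order -> :class:`TrajectoryFit`; exactly one fit
    carries ``selected=True`` when any model is significant.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.ndim != 1 or ages.shape != values.shape:
        raise ValueError("ages and values must be matching 1-D arrays")
    if np.ptp(ages) == 0:
        raise ValueError("degenerate design: all ages equal")
    fits = {}
    results = {}
    for order in orders:
        if len(ages) <= order + 1:
            raise ValueError(f"need n > {order + 1} for an order-{order} fit")
        X = sm.add_constant(np.column_stack([ages ** k for k in range(1, order + 1)]))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear design matrix")
        res = sm.OLS(values, X).fit()
        results[order] = res
        fits[order] = TrajectoryFit(
            response=response, order=order,
            coefficients=np.asarray(res.params, dtype=float),
            adjusted_r2=float(res.rsquared_adj),
            f_stat=float(max(res.fvalue, 0.0)),
            p_value=float(np.clip(res.f_pvalue, np.nextafter(0, 1), 1.0)))

    if rule == "adjusted_r2":
        significant = [o for o in fits if fits[o].p_value < alpha]
        if significant:
            best = max(sorted(significant), key=lambda o: (fits[o].adjusted_r2, -o))
            fits[best].selected = True
    elif rule == "nested_f":
        if set(orders) >= {1, 2}:
            quad_p = results[2].pvalues[-1]
            fits[2 if quad_p < alpha else 1].selected = True
        else:
            fits[min(orders)].selected = True
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return fits


def anova_from_summary(a: GroupSummary, b: GroupSummary,
                       factor: str = "group") -> GroupComparison:
    """One-way two-group ANOVA from published summary statistics.

    With pooled variance s^2 = [(n_a - 1) s_a^2 + (n_b - 1) s_b^2] /
    (n_a + n_b - 2), the statistic is
    F = (mean_a - mean_b)^2 / [s^2 (1/n_a + 1/n_b)] on (1, n_a + n_b - 2)
    degrees of freedom (identical to the squared two-sample t).  The effect
    size is partial eta^2 = F df_num / (F df_num + df_den).
    """
    df_num = 1
    df_den = a.n + b.n - 2
    pooled = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df_den
    diff = a.mean - b.mean
    if pooled <= 0:
        if diff == 0:
            f = 0.0
        else:
            warnings.warn("zero pooled variance with unequal means; F = inf")
            f = np.inf
    else:
        f = diff ** 2 / (pooled * (1.0 / a.n + 1.0 / b.n))
    if np.isinf(f):
        p, eta = np.nextafter(0, 1), 1.0
    else:
        p = float(sps.f.sf(f, df_num, df_den))
        p = float(np.clip(p, np.nextafter(0, 1), 1.0))
        eta = f * df_num / (f * df_num + df_den)
    return GroupComparison(factor=factor, f_stat=float(f), df_num=df_num,
                           df_den=df_den, p_value=p, partial_eta2=float(eta))


def ancova_group(values, groups, ages, factor: str = "group") -> GroupComparison:
    """ANCOVA ``value ~ group + age`` with a Type-II group test.

    The group F comes from Type-II sums of squares (each term adjusted for
    the other, no interaction); partial eta^2 = SS_group / (SS_group +
    SS_residual).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ages = np.asarray(ages, dtype=float)
    if len(values) < 4:
        raise ValueError("need n >= 4 for the ANCOVA")
    if len(np.unique(groups)) != 2:
        raise ValueError("exactly two non-empty groups required")
    df = pd.DataFrame({"value": values, "grp": groups.astype(str), "age": ages})
    for g in df["grp"].unique():
        if np.ptp(df.loc[df["grp"] == g, "age"]) == 0 and np.ptp(ages) == 0:
            raise ValueError("confounded design: age constant within groups")
    model = smf.ols("value ~ C(grp) + age", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("confounded design: group and age are collinear")
    table = sm.stats.anova_lm(model, typ=2)
    ss_group = float(table.loc["C(grp)", "sum_sq"])
    ss_resid = float(table.loc["Residual", "sum_sq"])
    f = float(table.loc["C(grp)", "F"])
    p = float(np.clip(table.loc["C(grp)", "PR(>F)"], np.nextafter(0, 1), 1.0))
    return GroupComparison(
        factor=factor, f_stat=max(f, 0.0), df_num=int(table.loc["C(grp)", "df"]),
        df_den=int(table.loc["Residual", "df"]), p_value=p,
        partial_eta2=ss_group / (ss_group + ss_resid), covariates=("age",))


def brainage_group_difference(scores, groups, ages=None,
                              test_group: str = "MNR",
                              reference_group: str = "CTR"):
    """Mean BrainAGE score difference (test - reference) plus the age ANCOVA.

    Returns ``(difference_years, GroupComparison or None)``; the ANCOVA is
    skipped (None) when ages are not supplied or n < 4.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    in_test = groups == test_group
    in_ref = groups == reference_group
    if not in_test.any() or not in_ref.any():
        raise ValueError(f"both groups {test_group!r} and {reference_group!r} "
                         "must be present")
    diff = float(scores[in_test].mean() - scores[in_ref].mean())
    comparison = None
    keep = in_test | in_ref
    if ages is not None and keep.sum() >= 4:
        comparison = ancova_group(scores[keep], groups[keep],
                                  np.asarray(ages, dtype=float)[keep])
    return diff, comparison
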