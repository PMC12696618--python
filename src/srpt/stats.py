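"""Repeated-measures statistics for the plasticity analyses.

Implements the classical within-subjects (repeated-measures) one-way ANOVA
and the two-way mixed design (between-subjects group x within-subjects
session), both with the Greenhouse-Geisser sphericity correction applied
unconditionally to within-subject terms, plus paired/unpaired t tests and
Sidak / Holm multiplicity adjustment for post hoc comparisons.

The Greenhouse-Geisser epsilon is estimated from the (pooled, for mixed
designs) sample covariance of the within-subject scores:

    epsilon = tr(C S C)^2 / ((k - 1) tr((C S C)^2)),   C = I - J/k,

clipped to its theoretical range [1/(k-1), 1].  Both numerator and
denominator degrees of freedom of within-subject F tests are multiplied by
epsilon, yielding the fractional dfs conventional in this literature.
Exact Dunnett / Tukey studentized-range post hocs are deliberately not
implemented; Sidak (or Holm) adjusted pairwise tests stand in for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RmDesign",
    "AnovaResult",
    "gg_epsilon",
    "rm_anova_oneway",
    "mixed_anova",
    "pairwise_posthoc",
    "sidak_adjust",
    "holm_adjust",
    "t_test",
]


@dataclass
class RmDesign:
    """Complete subjects x conditions table, optionally with a group factor."""

    values: np.ndarray                 # (n_subjects, k_levels), no missing cells
    within_levels: list
    subjects: list | None = None
    groups: np.ndarray | None = None   # per-subject between-factor labels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a subjects x conditions matrix")
        if np.isnan(self.values).any():
            raise ValueError("missing cells are not allowed in an RM design")
        if self.values.shape[1] != len(self.within_levels):
            raise ValueError("within_levels must match the number of columns")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if len(self.groups) != self.values.shape[0]:
                raise ValueError("one group label per subject required")

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        subject: str,
        within: str,
        value: str,
        between: str | None = None,
    ) -> "RmDesign":
        """Pivot a tidy long table into a complete RM design."""
        wide = df.pivot_table(index=subject, columns=within, values=value)
        if wide.isna().any().any():
            raise ValueError("missing cells after pivoting")
        groups = None
        if between is not None:
            lab = df.groupby(subject)[between].first()
            groups = lab.loc[wide.index].to_numpy()
        return cls(
            values=wide.to_numpy(),
            within_levels=list(wide.columns),
            subjects=list(wide.index),
            groups=groups,
        )


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    epsilon: float
    p: float
    method: str = "rm-anova-gg"


def gg_epsilon(values: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a subjects x conditions matrix."""
    Y = np.asarray(values, dtype=float)
    n, k = Y.shape
    if k < 2:
        raise ValueError("epsilon requires at least two conditions")
    S = np.cov(Y, rowvar=False, ddof=1)
    return _epsilon_from_cov(S, k)


def _epsilon_from_cov(S: np.ndarray, k: int) -> float:
    C = np.eye(k) - np.full((k, k), 1.0 / k)
    A = C @ S @ C
    denom = (k - 1) * np.trace(A @ A)
    if denom <= 0:
        return 1.0
    eps = np.trace(A) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_oneway(design: RmDesign) -> AnovaResult:
    """Classical one-way within-subjects F with GG-corrected dfs.

    Degenerate inputs follow the convention F = 0, p = 1 when there is no
    condition variance at all.
    """
    Y = design.values
    n, k = Y.shape
    if n < 3:
        raise ValueError("need at least three subjects")
    if k < 2:
        raise ValueError("need at least two within levels")
    grand = Y.mean()
    col_means = Y.mean(axis=0)
    row_means = Y.mean(axis=1)
    ss_cond = n * np.sum((col_means - grand) ** 2)
    resid = Y - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    eps = gg_epsilon(Y)
    df1 = (k - 1) * eps
    df2 = (k - 1) * (n - 1) * eps
    if ss_cond <= 0:
        return AnovaResult("within", 0.0, df1, df2, eps, 1.0)
    if ss_err <= 0:
        return AnovaResult("within", float("inf"), df1, df2, eps, 0.0)
    F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    p = float(sps.f.sf(F, df1, df2))
    return AnovaResult("within", float(F), df1, df2, eps, p)


def mixed_anova(design: RmDesign) -> list[AnovaResult]:
    """Two-way mixed ANOVA: between-group, within-session, interaction.

    The group factor is between-subjects; GG correction (epsilon pooled over
    group covariances) is applied to the within and interaction terms only.
    """
    if design.groups is None:
        raise ValueError("mixed design requires a between factor")
    Y = design.values
    n, k = Y.shape
    labels = pd.unique(design.groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    idx = {g: np.flatnonzero(design.groups == g) for g in labels}
    if any(len(v) < 2 for v in idx.values()):
        raise ValueError("each group needs at least two subjects")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    g = len(labels)

    ss_group = k * sum(
        len(rows) * (subj_means[rows].mean() - grand) ** 2 for rows in idx.values()
    )
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_subj_within = ss_subj - ss_group

    ss_cond = n * np.sum((col_means - grand) ** 2)
    ss_inter = 0.0
    for rows in idx.values():
        cell = Y[rows].mean(axis=0)
        gmean = subj_means[rows].mean()
        ss_inter += len(rows) * np.sum((cell - gmean - col_means + grand) ** 2)
    resid = np.zeros_like(Y)
    for rows in idx.values():
        cell = Y[rows].mean(axis=0)
        resid[rows] = Y[rows] - subj_means[rows][:, None] - cell[None, :] + subj_means[rows].mean()
    ss_err = np.sum(resid**2)

    # pooled within-group covariance for the sphericity estimate
    S = sum((len(rows) - 1) * np.cov(Y[rows], rowvar=False, ddof=1) for rows in idx.values())
    S = S / (n - g)
    eps = _epsilon_from_cov(S, k)

    df_group, df_sw = g - 1, n - g
    df_cond, df_inter, df_err = k - 1, (g - 1) * (k - 1), (n - g) * (k - 1)

    ms_sw = ss_subj_within / df_sw
    F_group = (ss_group / df_group) / ms_sw if ms_sw > 0 else float("inf")
    p_group = float(sps.f.sf(F_group, df_group, df_sw))

    ms_err = ss_err / df_err
    out = [AnovaResult("group", float(F_group), df_group, df_sw, 1.0, p_group,
                       method="mixed-anova")]
    for name, ss, df in (("within", ss_cond, df_cond), ("interaction", ss_inter, df_inter)):
        if ms_err > 0:
            F = (ss / df) * (1.0 / ms_err)
            p = float(sps.f.sf(F, df * eps, df_err * eps))
        else:
            F, p = float("inf"), 0.0
        out.append(AnovaResult(name, float(F), df * eps, df_err * eps, eps, p,
                               method="mixed-anova-gg"))
    return out


def sidak_adjust(p: float, m: int) -> float:
    """Sidak familywise adjustment: 1 - (1 - p)^m."""
    return float(1.0 - (1.0 - p) ** m)


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def t_test(x, y, paired: bool = False) -> tuple[float, float, float]:
    """Two-sided t test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per sample")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal lengths")
        d = x - y
        if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
            return 0.0, float(len(d) - 1), 1.0
        if d.std(ddof=1) == 0:
            raise ValueError("zero-variance differences")
        res = sps.ttest_rel(x, y)
        df = len(x) - 1
    else:
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            if np.isclose(x.mean(), y.mean()):
                return 0.0, float(len(x) + len(y) - 2), 1.0
            raise ValueError("zero-variance samples")
        res = sps.ttest_ind(x, y)
        df = len(x) + len(y) - 2
    return float(res.statistic), float(df), float(res.pvalue)


def pairwise_posthoc(
    design: RmDesign,
    comparisons: list[tuple] | None = None,
    method: str = "sidak",
    between: bool = False,
) -> pd.DataFrame:
    """Post hoc pairwise tests with familywise adjustment.

    Within mode (default): paired t tests between pairs of within levels
    (all pairs unless ``comparisons`` lists ``(level_a, level_b)`` tuples).
    Between mode: the two groups compared at each within level with
    unpaired t tests (the genotype-by-day style comparison).
    """
    if method not in ("sidak", "holm"):
        raise ValueError("method must be 'sidak' or 'holm'")
    rows = []
    if between:
        if design.groups is None:
            raise ValueError("between comparisons require a group factor")
        labels = pd.unique(design.groups)
        if len(labels) != 2:
            raise ValueError("between posthoc expects exactly two groups")
        a = design.values[design.groups == labels[0]]
        b = design.values[design.groups == labels[1]]
        levels = comparisons or list(design.within_levels)
        for lvl in levels:
            j = design.within_levels.index(lvl)
            t, df, p = t_test(a[:, j], b[:, j])
            rows.append((f"{labels[0]} vs {labels[1]} @ {lvl}", t, df, p))
    else:
        if comparisons is None:
            comparisons = [
                (a, b)
                for i, a in enumerate(design.within_levels)
                for b in design.within_levels[i + 1 :]
            ]
        for a, b in comparisons:
            ia = design.within_levels.index(a)
            ib = design.within_levels.index(b)
            t, df, p = t_test(design.values[:, ia], design.values[:, ib], paired=True)
            rows.append((f"{a} vs {b}", t, df, p))
    df_out = pd.DataFrame(rows, columns=["comparison", "t", "df", "p_unc"])
    m = len(df_out)
    if method == "sidak":
        df_out["p_adj"] = [sidak_adjust(p, m) for p in df_out["p_unc"]]
    else:
        df_out["p_adj"] = holm_adjust(df_out["p_unc"].to_numpy())
    df_out["method"] = method
    return df_out
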