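"""Group-comparison statistics for two-group vascular studies.

Implements the comparisons the morphometry feeds into: classical
pooled-variance (Student) two-tailed unpaired t-tests, a balanced two-way
repeated-measures (split-plot) ANOVA whose interaction term asks whether
the group difference varies across branch-length bins, Bonferroni
adjustment for the per-bin post-hoc comparisons, and Shapiro–Wilk normality
assessment.

The ANOVA is the balanced mixed design: group is between-subject, bin is
within-subject.  For g groups, n subjects per group and b bins, the
interaction F carries df = ((g-1)(b-1), (N-g)(b-1)) with N = g*n — e.g.
(3, 24) for 2 groups of 5 across 4 bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05  # conventional significance level used in study reports


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    adjustment: str = "none"
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def t_test_unpaired(x, y) -> TestResult:
    """Two-tailed unpaired Student's t-test (pooled variance, not Welch).

    ``t = (mean(x) - mean(y)) / (s_p * sqrt(1/n1 + 1/n2))`` with
    ``df = n1 + n2 - 2``.  Degenerate zero-variance inputs: equal means give
    ``t = 0, p = 1``; unequal means with zero pooled variance are an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return TestResult("student_t", 0.0, (float(df),), 1.0)
        raise ValueError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult("student_t", float(t), (float(df),), float(p))


def _stack_balanced(table: pd.DataFrame) -> tuple[np.ndarray, list, list]:
    """Pivot a long StudyTable into a (g, n, b) array; error on gaps."""
    required = {"sample", "group", "bin", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"StudyTable missing columns: {sorted(missing)}")
    groups = list(pd.unique(table["group"]))
    bins = list(pd.unique(table["bin"]))
    wide = table.pivot_table(
        index=["group", "sample"], columns="bin", values="value", aggfunc="first"
    )
    if wide.isna().any().any():
        holes = [
            f"{idx}/{col}" for idx, row in wide.iterrows() for col in wide.columns[row.isna()]
        ]
        raise ValueError(f"incomplete design; missing cells: {holes[:10]}")
    counts = wide.groupby(level="group").size()
    if counts.nunique() != 1:
        raise ValueError(f"unbalanced design; subjects per group: {counts.to_dict()}")
    n = int(counts.iloc[0])
    g, b = len(groups), len(bins)
    Y = np.empty((g, n, b), dtype=float)
    for gi, grp in enumerate(groups):
        block = wide.loc[grp]
        Y[gi] = block[bins].to_numpy()
    return Y, groups, bins


def rm_anova_interaction(
    table: pd.DataFrame, gg_correction: bool = False
) -> TestResult:
    """Group x bin interaction of a balanced two-way repeated-measures ANOVA.

    ``table`` is long-format with columns ``sample, group, bin, value``; each
    subject must have a value in every bin (complete, balanced design).
    Group is the between-subject factor, bin the within-subject factor.
    Returns the interaction F with df ``((g-1)(b-1), (N-g)(b-1))``.

    With ``gg_correction`` the Greenhouse–Geisser epsilon is estimated from
    the within-subject covariance and the corrected p (and epsilon) are
    reported alongside the uncorrected statistic.
    """
    Y, groups, bins = _stack_balanced(table)
    res = rm_anova_interaction_array(Y, gg_correction=gg_correction)
    res.extra.update({"groups": groups, "bins": bins})
    return res


def rm_anova_interaction_array(
    Y: np.ndarray, gg_correction: bool = False
) -> TestResult:
    """Interaction F from a complete balanced ``(groups, subjects, bins)``
    array — the computational core of :func:`rm_anova_interaction`."""
    Y = np.asarray(Y, dtype=float)
    g, n, b = Y.shape
    if g < 2 or b < 2:
        raise ValueError("need >= 2 groups and >= 2 bins")
    if n < 2:
        raise ValueError("need >= 2 subjects per group")
    m = Y.mean()
    m_g = Y.mean(axis=(1, 2))
    m_b = Y.mean(axis=(0, 1))
    m_gb = Y.mean(axis=1)
    m_gi = Y.mean(axis=2)
    ss_gb = n * float(((m_gb - m_g[:, None] - m_b[None, :] + m) ** 2).sum())
    resid = Y - m_gb[:, None, :] - m_gi[:, :, None] + m_g[:, None, None]
    ss_err = float((resid**2).sum())
    df1 = (g - 1) * (b - 1)
    df2 = (g * n - g) * (b - 1)
    F = (ss_gb / df1) / (ss_err / df2)
    p = float(sps.f.sf(F, df1, df2))
    extra: dict = {"n_per_group": n}
    adjustment = "none"
    if gg_correction:
        # pooled within-group covariance of the b repeated measures
        centered = (Y - m_gb[:, None, :]).reshape(g * n, b)
        S = centered.T @ centered / (g * n - g)
        d = S.diagonal().mean() - S.mean()
        denom = (b - 1) * ((S * S).sum() - 2 * b * (S.mean(axis=1) ** 2).sum() + b * b * S.mean() ** 2)
        eps = (b * d) ** 2 / denom if denom > 0 else 1.0
        eps = float(min(1.0, max(eps, 1.0 / (b - 1))))
        p = float(sps.f.sf(F, df1 * eps, df2 * eps))
        extra["gg_epsilon"] = eps
        adjustment = "greenhouse-geisser"
    return TestResult(
        "rm_anova_interaction", float(F), (float(df1), float(df2)), p,
        adjustment=adjustment, extra=extra,
    )


def bonferroni_adjust(p_values) -> np.ndarray:
    """Bonferroni adjustment: ``p_adj = min(1, m * p)`` with m = len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def shapiro_wilk(x) -> TestResult:
    """Shapiro–Wilk normality test (Royston approximation, via SciPy).

    Requires 3 <= n <= 5000 and a non-constant sample.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk p-approximation valid only to n = 5000")
    if np.ptp(x) == 0:
        raise ValueError("W undefined for a constant sample")
    W, p = sps.shapiro(x)
    return TestResult("shapiro_wilk", float(W), (float(x.size),), float(p))


def posthoc_bin_t_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Per-bin two-group Student t-tests with Bonferroni over the bins.

    The post-hoc family following a significant interaction: one pairwise
    group comparison per bin, m = number of bins.  Returns a tidy frame with
    ``bin, t, df, p, p_bonferroni, m``.
    """
    Y, groups, bins = _stack_balanced(table)
    if Y.shape[0] != 2:
        raise ValueError("post-hoc pairwise comparisons expect exactly 2 groups")
    rows = []
    for bi, bin_label in enumerate(bins):
        res = t_test_unpaired(Y[0, :, bi], Y[1, :, bi])
        rows.append(
            {"bin": bin_label, "t": res.statistic, "df": res.df[0], "p": res.p_value}
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni_adjust(out["p"].to_numpy())
    out["m"] = len(bins)
    return out


def group_summary(values: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Per-group mean ± SEM for a tidy (group, value) frame."""
    def sem(v):
        v = np.asarray(v, float)
        return v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan

    return (
        values.groupby("group")[value_col]
        .agg(mean="mean", sem=sem, n="size")
        .reset_index()
    )
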