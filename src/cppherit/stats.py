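"""Statistical comparisons for behavioral phenotypes.

Paired and unpaired t-tests, a classical mixed-design (split-plot)
repeated-measures ANOVA, Bonferroni thresholds with two-significant-figure
display rounding, and pairwise Pearson correlation matrices. All tests are
two-sided by default; sidedness is a flag where meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "CorrelationResult",
    "DegenerateDataError",
    "UnbalancedDesignError",
    "bonferroni_alpha",
    "display_alpha",
    "paired_t",
    "unpaired_t",
    "rm_anova",
    "correlation_matrix",
]


class DegenerateDataError(ValueError):
    """Data carry no variance where the statistic requires some."""


class UnbalancedDesignError(ValueError):
    """The repeated-measures design is incomplete or unbalanced."""


@dataclass(frozen=True)
class TestResult:
    """A single test statistic with its reference distribution and decision."""

    name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    alpha_used: float = 0.05
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha_used)


def bonferroni_alpha(family_alpha: float, k: int) -> float:
    """Per-comparison threshold ``family_alpha / k`` for ``k`` comparisons."""
    if not (0.0 < family_alpha <= 1.0):
        raise ValueError("family_alpha must be in (0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return family_alpha / k


def display_alpha(alpha: float) -> float:
    """Round a threshold to two significant figures for reporting.

    Matches the printed conventions 0.05/3 -> 0.017, 0.05/4 -> 0.013,
    0.05/6 -> 0.0083. Internal comparisons should use the unrounded value.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    exponent = math.floor(math.log10(abs(alpha)))
    return round(alpha, -exponent + 1)


def _sided_p(t: float, df: float, sided: str) -> float:
    if sided == "two":
        return float(2.0 * sps.t.sf(abs(t), df))
    if sided == "one":
        return float(sps.t.sf(t, df))
    raise ValueError("sided must be 'one' or 'two'")


def paired_t(
    x, y, alpha: float = 0.05, sided: str = "two", name: str = "paired_t"
) -> TestResult:
    """Classical paired t-test on the differences ``x - y`` (df = n - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        # zero variance of differences: degenerate but well-defined direction
        if d.mean() == 0.0:
            return TestResult(name, 0.0, n - 1, 1.0, alpha, degenerate=True)
        t = math.inf if d.mean() > 0 else -math.inf
        return TestResult(name, t, n - 1, 0.0, alpha, degenerate=True)
    t = d.mean() / (sd / math.sqrt(n))
    return TestResult(name, float(t), n - 1, _sided_p(t, n - 1, sided), alpha)


def unpaired_t(
    x,
    y,
    pooled: bool = True,
    alpha: float = 0.05,
    sided: str = "two",
    name: str = "unpaired_t",
) -> TestResult:
    """Two-sample t-test (pooled-variance by default, Welch otherwise)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        if x.mean() == y.mean():
            df = x.size + y.size - 2
            return TestResult(name, 0.0, df, 1.0, alpha, degenerate=True)
        raise DegenerateDataError("both groups constant with different means")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    t, df = float(res.statistic), float(res.df)
    return TestResult(name, t, df, _sided_p(t, df, sided), alpha)


def _gg_epsilon(cell: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from a subjects x days matrix."""
    S = np.cov(cell, rowvar=False)
    b = S.shape[0]
    C = np.eye(b) - np.ones((b, b)) / b
    M = C @ S @ C
    lam = np.linalg.eigvalsh(M)
    num = lam.sum() ** 2
    den = (b - 1) * np.sum(lam**2)
    return float(num / den) if den > 0 else 1.0


def rm_anova(
    table: pd.DataFrame,
    subject: str = "animal_id",
    within: str = "day",
    value: str = "value",
    between: str | None = None,
    alpha: float = 0.05,
    correction: str | None = None,
) -> dict[str, TestResult]:
    """Mixed-design (split-plot) repeated-measures ANOVA on a long table.

    Requires a balanced complete design: every subject measured at every
    level of ``within``, and (when ``between`` is given) equal numbers of
    subjects per group. Returns F-tests keyed ``"within"`` and, with a
    between factor, ``"between"`` and ``"interaction"``; error terms follow
    the standard split-plot decomposition (subjects-within-groups error for
    the between factor, subject x within error for the rest), giving the
    uncorrected df pattern. ``correction="gg"`` applies Greenhouse-Geisser
    df scaling to the within and interaction tests.
    """
    cols = [subject, within, value] + ([between] if between else [])
    df = table.loc[:, cols].copy()
    if df[value].isna().any():
        raise UnbalancedDesignError("missing values in the response")
    wide = df.pivot_table(index=subject, columns=within, values=value, aggfunc="count")
    if wide.isna().any().any() or not (wide == 1).all().all():
        raise UnbalancedDesignError(
            "every subject must be measured exactly once at every within level"
        )
    days = sorted(df[within].unique())
    b = len(days)
    cell = df.pivot(index=subject, columns=within, values=value).loc[:, days]

    if between is not None:
        group_of = df.groupby(subject)[between].agg(lambda s: s.iloc[0])
        if df.groupby(subject)[between].nunique().max() > 1:
            raise UnbalancedDesignError("a subject appears in more than one group")
        groups = sorted(group_of.unique())
        a = len(groups)
        counts = group_of.value_counts()
        if counts.nunique() > 1:
            raise UnbalancedDesignError("unequal group sizes (unbalanced design)")
        n = int(counts.iloc[0])
    else:
        groups, a = [None], 1
        group_of = pd.Series("all", index=cell.index)
        n = cell.shape[0]

    Y = cell.to_numpy(dtype=float)  # subjects x days
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    day_means = Y.mean(axis=0)
    glabels = group_of.loc[cell.index].to_numpy()

    ss_total = float(((Y - grand) ** 2).sum())
    ss_between_subj = float(b * ((subj_means - grand) ** 2).sum())
    if a > 1:
        gmeans = {g: Y[glabels == g].mean() for g in groups}
        ss_group = float(n * b * sum((gmeans[g] - grand) ** 2 for g in groups))
        cellmeans = np.array([Y[glabels == g].mean(axis=0) for g in groups])
        ss_int = float(
            n
            * (
                (
                    cellmeans
                    - np.array([gmeans[g] for g in groups])[:, None]
                    - day_means[None, :]
                    + grand
                )
                ** 2
            ).sum()
        )
    else:
        ss_group = 0.0
        ss_int = 0.0
    ss_subj_within = ss_between_subj - ss_group
    ss_day = float(a * n * ((day_means - grand) ** 2).sum())
    ss_err_within = ss_total - ss_between_subj - ss_day - ss_int

    df_group = a - 1
    df_subj_within = a * (n - 1)
    df_day = b - 1
    df_int = (a - 1) * (b - 1)
    df_err_within = a * (n - 1) * (b - 1)

    eps = _gg_epsilon(Y) if correction == "gg" else 1.0
    if correction not in (None, "gg"):
        raise ValueError("correction must be None or 'gg'")

    def ftest(name, ss_num, df_num, ss_den, df_den, scale=1.0):
        if df_num == 0 or df_den == 0:
            raise UnbalancedDesignError(f"no degrees of freedom for {name}")
        ms_den = ss_den / df_den
        if ms_den == 0.0:
            f = 0.0 if ss_num == 0.0 else math.inf
            p = 1.0 if ss_num == 0.0 else 0.0
            return TestResult(name, f, (df_num, df_den), p, alpha, degenerate=True)
        f = (ss_num / df_num) / ms_den
        p = float(sps.f.sf(f, df_num * scale, df_den * scale))
        return TestResult(name, float(f), (df_num, df_den), p, alpha)

    out = {"within": ftest("within", ss_day, df_day, ss_err_within, df_err_within, eps)}
    if a > 1:
        out["between"] = ftest("between", ss_group, df_group, ss_subj_within, df_subj_within)
        out["interaction"] = ftest(
            "interaction", ss_int, df_int, ss_err_within, df_err_within, eps
        )
    return out


@dataclass(frozen=True)
class CorrelationResult:
    """Pairwise Pearson correlations with two-sided p-values."""

    traits: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def correlation_matrix(
    phenos: pd.DataFrame, traits: list[str] | None = None, min_n: int = 3
) -> CorrelationResult:
    """Pairwise Pearson r over ``traits`` with p from the t transform of r.

    Uses pairwise-complete observations. A constant trait (or a pair with
    fewer than ``min_n`` complete observations) yields missing r and p,
    never zero.
    """
    if traits is None:
        traits = [c for c in phenos.columns if pd.api.types.is_numeric_dtype(phenos[c])]
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            xy = phenos[[traits[i], traits[j]]].dropna()
            m = len(xy)
            n[i, j] = n[j, i] = m
            if m < min_n:
                continue
            x = xy.iloc[:, 0].to_numpy(dtype=float)
            y = xy.iloc[:, 1].to_numpy(dtype=float)
            if x.std() == 0.0 or y.std() == 0.0:
                continue  # undefined correlation stays missing
            if i == j:
                r[i, i], p[i, i] = 1.0, 0.0
                continue
            res = sps.pearsonr(x, y)
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    idx = list(traits)
    return CorrelationResult(
        tuple(traits),
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(n, index=idx, columns=idx),
    )
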