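"""Cross-cluster and cross-group statistics.

The suite mirrors a conventional between-subject analysis of cluster
differences: one-way fixed-effects ANOVA with eta-squared, Tukey-Kramer HSD
post-hoc comparisons (studentized-range distribution, unequal group sizes),
pooled-variance two-sample t tests with Cohen's d, the Yates-corrected 2x2
chi-square, and a multinomial goodness-of-fit test of observed category
counts against expected proportions (uniform by default). Missing values
are dropped listwise before any test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import DataError


@dataclass
class AnovaResult:
    ss_between: float
    ss_residual: float
    df_between: int
    df_residual: int
    ms_between: float
    ms_residual: float
    F: float
    eta_sq: float
    p: float


@dataclass
class TukeyResult:
    """One Tukey-Kramer pairwise comparison."""

    group_a: object
    group_b: object
    diff: float          # mean(b) - mean(a)
    ci_low: float
    ci_high: float
    p_adj: float


@dataclass
class TTestResult:
    t: float
    df: int
    ci95: tuple
    cohens_d: float
    p: float


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    yates: bool


@dataclass
class MultinomialGofResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray


def _clean_groups(groups):
    """Drop NaNs within groups; drop empty groups with a warning."""
    cleaned = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 1:
            warnings.warn("one_way_anova: dropping a group with no observations")
            continue
        cleaned.append(arr)
    return cleaned


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA over a sequence of samples."""
    groups = _clean_groups(groups)
    if len(groups) < 2:
        raise DataError("one_way_anova: need at least 2 non-empty groups")
    all_vals = np.concatenate(groups)
    n = all_vals.size
    k = len(groups)
    if n - k < 2:
        raise DataError("one_way_anova: need at least 2 residual degrees of freedom")
    grand = all_vals.mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_residual = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    return anova_from_sums(ss_between, k - 1, ss_residual, n - k)


def anova_from_sums(ss_between: float, df_between: int,
                    ss_residual: float, df_residual: int) -> AnovaResult:
    """Assemble the ANOVA table from sums of squares and degrees of freedom."""
    ms_b = ss_between / df_between
    ms_r = ss_residual / df_residual
    F = ms_b / ms_r
    return AnovaResult(
        ss_between=ss_between, ss_residual=ss_residual,
        df_between=df_between, df_residual=df_residual,
        ms_between=ms_b, ms_residual=ms_r, F=float(F),
        eta_sq=float(ss_between / (ss_between + ss_residual)),
        p=float(sps.f.sf(F, df_between, df_residual)),
    )


def tukey_from_summary(means, ns, mse: float, df_residual: int,
                       alpha: float = 0.05, names=None) -> list[TukeyResult]:
    """Tukey-Kramer comparisons from group means, sizes and the ANOVA MSE.

    The confidence half-width for a pair (a, b) is
    q(1-alpha, K, df) * sqrt(mse/2 * (1/n_a + 1/n_b)); the adjusted p comes
    from the studentized-range distribution.
    """
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    K = means.size
    if K < 2:
        raise DataError("tukey: need at least 2 groups")
    names = list(names) if names is not None else list(range(K))
    q_crit = sps.studentized_range.ppf(1.0 - alpha, K, df_residual)
    if not np.isfinite(q_crit):
        raise DataError("tukey: studentized-range quantile unavailable")
    results = []
    for a in range(K):
        for b in range(a + 1, K):
            se = math.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            diff = means[b] - means[a]
            q_stat = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q_stat, K, df_residual))
            half = q_crit * se
            results.append(
                TukeyResult(
                    group_a=names[a], group_b=names[b], diff=float(diff),
                    ci_low=float(diff - half), ci_high=float(diff + half),
                    p_adj=min(max(p_adj, 0.0), 1.0),
                )
            )
    return results


def tukey_hsd(groups, alpha: float = 0.05, names=None) -> list[TukeyResult]:
    """Tukey-Kramer HSD from raw data: runs the ANOVA, then all pairs."""
    groups = _clean_groups(groups)
    anova = one_way_anova(groups)
    means = [g.mean() for g in groups]
    ns = [g.size for g in groups]
    return tukey_from_summary(means, ns, anova.ms_residual, anova.df_residual,
                              alpha=alpha, names=names)


def pooled_t_test(m1: float, sd1: float, n1: int,
                  m2: float, sd2: float, n2: int) -> TTestResult:
    """Two-sample pooled-variance t test from summary statistics.

    Cohen's d uses the pooled SD (no small-sample correction); the 95% CI is
    for the mean difference m1 - m2.
    """
    if n1 < 2 or n2 < 2:
        raise DataError("pooled_t_test: need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    if sp2 <= 0:
        raise DataError("pooled_t_test: zero pooled variance")
    sp = math.sqrt(sp2)
    se = sp * math.sqrt(1.0 / n1 + 1.0 / n2)
    diff = m1 - m2
    t = diff / se
    tcrit = sps.t.ppf(0.975, df)
    return TTestResult(
        t=float(t), df=int(df),
        ci95=(float(diff - tcrit * se), float(diff + tcrit * se)),
        cohens_d=float(diff / sp),
        p=float(2.0 * sps.t.sf(abs(t), df)),
    )


def t_test_raw(x, y) -> TTestResult:
    """Pooled t test from raw samples (NaNs dropped)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    return pooled_t_test(x.mean(), x.std(ddof=1), x.size,
                         y.mean(), y.std(ddof=1), y.size)


def chi2_2x2(table, yates: bool = True) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 count table, Yates-corrected by default."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise DataError("chi2_2x2: need a 2x2 table of non-negative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DataError("chi2_2x2: zero margin")
    chi2, p, dof, _ = sps.chi2_contingency(obs, correction=yates)
    return ChiSquareResult(chi2=float(chi2), df=int(dof), p=float(p), yates=yates)


def multinomial_gof(observed, proportions=None) -> MultinomialGofResult:
    """Chi-square goodness of fit of category counts to expected proportions.

    ``proportions`` defaults to uniform across the categories, which is the
    test applied to per-cluster diagnosis counts.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2 or (obs < 0).any():
        raise DataError("multinomial_gof: need >= 2 non-negative counts")
    total = obs.sum()
    if total <= 0:
        raise DataError("multinomial_gof: total count must be positive")
    if proportions is None:
        proportions = np.full(obs.size, 1.0 / obs.size)
    proportions = np.asarray(proportions, dtype=float)
    expected = total * proportions
    if (expected == 0).any():
        raise DataError("multinomial_gof: zero expected cell")
    chi2, p = sps.chisquare(obs, f_exp=expected)
    return MultinomialGofResult(chi2=float(chi2), df=obs.size - 1, p=float(p), expected=expected)
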