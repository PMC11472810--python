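"""Descriptive epidemiology: prevalence, sex differences and score contrasts.

Conventions match common practice for registry questionnaire studies:
Wald (normal-approximation) confidence intervals for proportions (Wilson
available by flag), Pearson chi-square without continuity correction for
the 2x2 sex-by-trait table, a Woolf log-scale interval for the odds ratio,
and a pooled-variance two-sample t-test computed from summary statistics.
Twins are treated as independent individuals in these descriptive
intervals; pair clustering enters only through the twin models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PrevalenceResult",
    "Association2x2Result",
    "SummaryTTestResult",
    "prevalence",
    "sex_difference_chi2",
    "odds_ratio",
    "pooled_t_test",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class PrevalenceResult:
    affected_count: int
    total: int
    proportion: float
    ci_low: float
    ci_high: float
    method: str

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion


@dataclass
class Association2x2Result:
    chi2: float | None = None
    df: int | None = None
    p: float | None = None
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None


@dataclass
class SummaryTTestResult:
    t: float
    df: int
    p: float
    mean_difference: float


def prevalence(affected: int, total: int, method: str = "wald",
               level: float = 0.95) -> PrevalenceResult:
    """Point prevalence with a 95% CI (Wald by default, Wilson by flag)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= affected <= total:
        raise ValueError("affected must lie between 0 and total")
    prop = affected / total
    sm_method = {"wald": "normal", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"method must be 'wald' or 'wilson', got {method!r}")
    lo, hi = proportion_confint(affected, total, alpha=1 - level, method=sm_method)
    return PrevalenceResult(
        affected_count=int(affected), total=int(total), proportion=prop,
        ci_low=float(max(0.0, lo)), ci_high=float(min(1.0, hi)), method=method,
    )


def _check_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    return t


def sex_difference_chi2(table) -> Association2x2Result:
    """Pearson chi-square (df = 1, no continuity correction) on a 2x2 table."""
    t = _check_2x2(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return Association2x2Result(chi2=float(chi2), df=int(df), p=float(p))


def odds_ratio(table, level: float = 0.95) -> Association2x2Result:
    """Cross-product odds ratio with a Woolf (log-scale) confidence interval.

    Zero cells get the conventional 0.5 continuity correction (applied to
    all four cells).
    """
    t = _check_2x2(table)
    if (t == 0).any():
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return Association2x2Result(
        odds_ratio=float(or_),
        or_ci_low=float(math.exp(math.log(or_) - z * se)),
        or_ci_high=float(math.exp(math.log(or_) + z * se)),
    )


def pooled_t_test(mean1: float, sd1: float, n1: int,
                  mean2: float, sd2: float, n2: int) -> SummaryTTestResult:
    """Two-sample pooled-variance t-test from summary statistics.

    The t statistic is oriented as group1 minus group2, so its sign matches
    the sign of the mean difference; p is two-sided with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return SummaryTTestResult(t=float(t), df=int(n1 + n2 - 2), p=float(p),
                              mean_difference=float(mean1 - mean2))
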