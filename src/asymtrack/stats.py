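"""Thin wrappers around the standard two-sample and paired tests.

All tests are two-sided and reported with raw p-values (no multiple-testing
correction is applied anywhere in the pipeline; every comparison is
reported with its n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "welch_ttest", "paired_ttest", "mann_whitney", "wilson_interval"]

EXACT_MANN_WHITNEY_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    df: float | None = None


def welch_ttest(a, b) -> TestResult:
    """Unpaired two-sample t-test with Welch's correction (unequal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        test="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        df=float(res.df),
    )


def paired_ttest(a, b) -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired test needs equal-length samples")
    res = sps.ttest_rel(a, b)
    return TestResult(
        test="paired_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        df=float(len(a) - 1),
    )


def mann_whitney(a, b) -> TestResult:
    """Mann-Whitney U; exact null distribution for small samples, normal
    approximation (tie-corrected) when either group exceeds
    ``EXACT_MANN_WHITNEY_MAX_N``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    method = "exact" if max(len(a), len(b)) <= EXACT_MANN_WHITNEY_MAX_N else "asymptotic"
    try:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses ties; fall back to the tie-corrected approximation
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(
        test="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
    )


def wilson_interval(count: int, nobs: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    return float(lo), float(hi)
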