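"""Shared statistical tests.

Thin, validated wrappers around scipy: Pearson chi-square on 2x2 contingency
tables (no continuity correction, matching the large-count regime these
comparisons live in) and paired / unpaired t-tests with defined behaviour in
the degenerate zero-variance cases the pipeline can produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    pvalue: float


def chi_square(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0):
        raise ValueError("contingency table cells must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    res = sps.chi2_contingency(table, correction=correction)
    return TestResult(statistic=float(res.statistic), df=float(res.dof), pvalue=float(res.pvalue))


def paired_t(x, y) -> TestResult:
    """Student's paired t-test.

    Identical samples (zero-variance, zero-mean differences) return t = 0,
    P = 1 instead of scipy's NaN; zero-variance nonzero-mean differences
    return P = 0 (the difference is exact).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return TestResult(statistic=0.0, df=float(x.size - 1), pvalue=1.0)
        return TestResult(
            statistic=float(np.sign(d.mean()) * np.inf), df=float(x.size - 1), pvalue=0.0
        )
    res = sps.ttest_rel(x, y)
    return TestResult(statistic=float(res.statistic), df=float(x.size - 1), pvalue=float(res.pvalue))


def unpaired_t(x, y, equal_var: bool = True) -> TestResult:
    """Student's two-sample t-test (equal variances by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per group")
    if np.allclose(np.concatenate([x, y]).std(ddof=1), 0.0):
        return TestResult(statistic=0.0, df=float(x.size + y.size - 2), pvalue=1.0)
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = x.size + y.size - 2 if equal_var else float("nan")
    return TestResult(statistic=float(res.statistic), df=float(df), pvalue=float(res.pvalue))


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg q-values (optional extension; raw P stays primary)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(ranked)
    q[order] = np.clip(ranked, 0, 1)
    return q
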