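"""t tests and multiple-comparison control for reconfiguration contrasts.

Two-sided classical t tests throughout (scipy under the hood), with a
degenerate-sample flag instead of a spurious p value when the sample
variance is zero.  Family-wise control is a strict Bonferroni threshold
(family of 10 community pairs -> alpha 0.005); edgewise discovery control
is the Benjamini-Yekutieli step-up, whose sum(1/i) factor is valid under
arbitrary dependence between edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidConfigError

__all__ = [
    "TestResult",
    "one_sample_t",
    "one_sample_t_many",
    "paired_t",
    "bonferroni",
    "fdr_by",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    pvalue: float
    degenerate: bool = False


def one_sample_t(diffs, popmean: float = 0.0) -> TestResult:
    """Two-sided one-sample t test against ``popmean``.

    Zero sample variance yields ``degenerate=True`` with NaN statistic and
    p value (a p of 0 is never emitted).
    """
    x = np.asarray(diffs, dtype=float).ravel()
    if len(x) < 2:
        raise InvalidConfigError("need at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise InvalidConfigError("observations must be finite")
    if np.ptp(x) == 0.0:
        return TestResult(statistic=np.nan, df=len(x) - 1, pvalue=np.nan,
                          degenerate=True)
    res = sp_stats.ttest_1samp(x, popmean)
    return TestResult(statistic=float(res.statistic), df=len(x) - 1,
                      pvalue=float(res.pvalue))


def one_sample_t_many(x: np.ndarray, axis: int = 0):
    """Columnwise one-sample t tests against 0 along ``axis``.

    Returns ``(t, p, degenerate)`` arrays; degenerate (zero-variance)
    columns carry NaN statistic and p value.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[axis] < 2:
        raise InvalidConfigError("need at least 2 observations")
    degenerate = np.ptp(x, axis=axis) == 0.0
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate columns trip scipy's precision-loss warning; they are
        # masked to NaN below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sp_stats.ttest_1samp(x, 0.0, axis=axis)
    t = np.where(degenerate, np.nan, res.statistic)
    p = np.where(degenerate, np.nan, res.pvalue)
    return t, p, degenerate


def paired_t(a, b) -> TestResult:
    """Paired t test: one-sample test on the elementwise differences."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise InvalidConfigError("paired samples must have equal length")
    return one_sample_t(a - b)


def bonferroni(pvals, family_size: int | None = None, alpha: float = 0.05):
    """Strict Bonferroni significance flags: p < alpha / family_size.

    Returns ``(flags, corrected_alpha)``.  ``family_size`` defaults to the
    number of p values; the 10-pair community family gives the 0.005
    threshold.  The boundary is excluded (p exactly at the corrected alpha
    is not significant).
    """
    p = np.asarray(pvals, dtype=float)
    if family_size is None:
        family_size = p.size
    if family_size < 1:
        raise InvalidConfigError("family_size must be >= 1")
    corrected = alpha / family_size
    return p < corrected, corrected


def fdr_by(pvals, q: float = 0.05):
    """Benjamini-Yekutieli step-up control of the false discovery rate.

    Returns ``(flags, adjusted)`` where adjusted values include the
    c(m) = sum_{i<=m} 1/i dependence factor and are monotone from the
    largest rank down, clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidConfigError("p values must lie in [0, 1]")
    shape = p.shape
    reject, adjusted, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_by")
    return reject.reshape(shape), adjusted.reshape(shape)
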