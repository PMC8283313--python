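"""Shared statistical helpers.

Thin wrappers around scipy/statsmodels that add the degenerate-input
conventions used throughout the pipeline (zero-variance t-tests, undefined
correlations) so that every caller handles edge cases identically.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ttest_matrix", "ttest_two_sample", "benjamini_hochberg", "pearson", "PearsonResult"]


def ttest_matrix(a: np.ndarray, b: np.ndarray, equal_var: bool = False) -> np.ndarray:
    """Row-wise two-sided two-sample t-test p-values.

    ``a`` and ``b`` are 2-D arrays (features x replicates). Welch by default.
    Conventions for degenerate rows:

    * both groups have zero variance and equal means -> p = 1
    * both groups have zero variance and different means -> p = 0
    * fewer than 2 replicates in either group, or non-finite input -> NaN
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("ttest_matrix expects 2-D arrays")
    if a.shape[1] < 2 or b.shape[1] < 2:
        return np.full(a.shape[0], np.nan)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # scipy warns about precision loss on near-identical rows; those rows
        # are overridden by the zero-variance conventions below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    both_zero = (va == 0) & (vb == 0)
    if both_zero.any():
        same = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[both_zero] = np.where(same[both_zero], 1.0, 0.0)
    bad = ~np.isfinite(a).all(axis=1) | ~np.isfinite(b).all(axis=1)
    p[bad] = np.nan
    return p


def ttest_two_sample(a, b, equal_var: bool = False) -> float:
    """Scalar two-sided two-sample t-test with the same degenerate conventions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        return float("nan")
    return float(ttest_matrix(a[None, :], b[None, :], equal_var=equal_var)[0])


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values; NaN p-values propagate as NaN."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass(frozen=True)
class PearsonResult:
    r: float
    r_squared: float
    p_value: float
    n: int
    defined: bool = True


def pearson(x, y) -> PearsonResult:
    """Pearson correlation with NaN filtering.

    Returns ``defined=False`` (NaN statistics) when fewer than 3 complete
    pairs remain or either variable has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    n = int(m.sum())
    if n < 3 or np.std(x[m]) == 0 or np.std(y[m]) == 0:
        return PearsonResult(float("nan"), float("nan"), float("nan"), n, defined=False)
    r, p = stats.pearsonr(x[m], y[m])
    return PearsonResult(float(r), float(r) ** 2, float(p), n)
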