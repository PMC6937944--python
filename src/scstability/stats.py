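"""Shared statistical utilities: BH correction and two-sample t tests.

Every multiple-testing correction in the package goes through
:func:`bh_adjust` so that the step-up procedure has a single implementation
and a single test surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTestError, InputError

__all__ = ["bh_adjust", "t_test", "TTestResult"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (untested hypotheses) are passed through as NaN and do not
    count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@dataclass(frozen=True)
class TTestResult:
    """Student t test outcome (two-sided)."""

    statistic: float
    df: float
    pvalue: float
    paired: bool
    n1: int
    n2: int


def t_test(x, y, paired: bool = False) -> TTestResult:
    """Two-sided Student t test of two groups of sample-level values.

    Paired variant tests the within-pair differences; it refuses to run when
    the differences have zero variance (the t statistic is then 0/0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise InputError("paired test requires equal-length groups")
        if x.size < 2:
            raise InputError("paired t test needs at least 2 pairs")
        d = x - y
        if np.allclose(d, d[0]) and not np.isclose(d[0], 0.0):
            raise DegenerateTestError("degenerate paired test: zero-variance differences")
        if np.allclose(d, 0.0):
            # identical pairs: mean difference 0 with no variance -> t = 0, p = 1
            return TTestResult(0.0, float(x.size - 1), 1.0, True, x.size, y.size)
        res = sps.ttest_rel(x, y)
        return TTestResult(float(res.statistic), float(x.size - 1), float(res.pvalue), True, x.size, y.size)
    if x.size < 2 or y.size < 2:
        raise InputError("unpaired t test needs at least 2 observations per group")
    if np.allclose(x, x.mean()) and np.allclose(y, y.mean()) and np.isclose(x.mean(), y.mean()):
        return TTestResult(0.0, float(x.size + y.size - 2), 1.0, False, x.size, y.size)
    res = sps.ttest_ind(x, y)
    return TTestResult(
        float(res.statistic), float(x.size + y.size - 2), float(res.pvalue), False, x.size, y.size
    )
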