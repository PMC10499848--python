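"""Normality-gated paired comparisons and one-way ANOVA for DSC tables.

The comparison protocol for two paired samples of model performances is:

1. Shapiro-Wilk on the paired differences at alpha = 0.05;
2. if normality is not rejected, a paired Student t-test, otherwise a
   two-sided Wilcoxon signed-rank test (exact null distribution for
   n <= 25, zero differences dropped);
3. significance at p < 0.05, two-sided throughout.

The gate is applied to the paired differences (the t-test's normality
assumption concerns the differences, not the two samples separately).
Groups of more than two samples are compared with a standard one-way
ANOVA.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "gated_paired_compare", "oneway_anova"]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one statistical comparison."""

    test_used: str  # 'paired-t' | 'wilcoxon' | 'anova' | 'degenerate'
    statistic: float
    p_value: float
    significant: bool
    direction: str | None = None  # 'a' or 'b' larger, when significant
    degenerate: bool = False
    shapiro_p: float | None = None


def gated_paired_compare(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Compare two paired samples with the normality-gated protocol.

    Identical samples (all differences zero) yield a degenerate result with
    no defined test statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1D and of equal length")
    if len(x) < 3:
        raise ValueError("paired comparison requires n >= 3")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    d = x - y
    if np.all(d == 0):
        return ComparisonResult(
            test_used="degenerate", statistic=float("nan"),
            p_value=1.0, significant=False, degenerate=True,
        )
    if np.ptp(d) == 0:
        # constant nonzero differences: Shapiro is undefined; treat as a
        # maximal departure from normality and use the rank test
        shapiro_p = 0.0
    else:
        shapiro_p = float(sps.shapiro(d).pvalue)
    if shapiro_p >= alpha:
        res = sps.ttest_rel(x, y)
        test_used = "paired-t"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        nz = d[d != 0]  # zero differences dropped (Wilcoxon convention)
        if nz.size == 0:  # pragma: no cover - covered by the all-zero branch
            return ComparisonResult("degenerate", float("nan"), 1.0, False,
                                    degenerate=True, shapiro_p=shapiro_p)
        method = "exact" if nz.size <= 25 else "approx"
        res = sps.wilcoxon(nz, zero_method="wilcox",
                           alternative="two-sided", method=method)
        test_used = "wilcoxon"
        stat, p = float(res.statistic), float(res.pvalue)
    significant = p < alpha
    direction = None
    if significant:
        direction = "a" if float(np.mean(d)) > 0 else "b"
    return ComparisonResult(
        test_used=test_used, statistic=stat, p_value=p,
        significant=significant, direction=direction, shapiro_p=shapiro_p,
    )


def oneway_anova(groups: Sequence[Sequence[float]],
                 alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA over two or more groups (F statistic and p-value)."""
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.ndim != 1 or len(a) < 2 for a in arrays):
        raise ValueError("each group must be 1D with length >= 2")
    if np.ptp(np.concatenate(arrays)) == 0:
        return ComparisonResult("degenerate", float("nan"), 1.0, False,
                                degenerate=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.f_oneway(*arrays)
    stat, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(stat):
        return ComparisonResult("degenerate", stat, 1.0, False,
                                degenerate=True)
    return ComparisonResult(
        test_used="anova", statistic=stat, p_value=p,
        significant=p < alpha,
    )
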