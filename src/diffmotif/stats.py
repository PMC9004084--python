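"""Statistical tests used across the analyses.

Wilcoxon rank-sum (exact for small tie-free samples, normal approximation with
tie and continuity corrections otherwise), Benjamini-Hochberg adjustment,
one-sided Fisher r-to-z comparison of two correlations, and Bonferroni scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    p: float
    sidedness: str  # "one" or "two"
    n1: int
    n2: int
    note: str = ""


def wilcoxon_rank_sum(x, y, sidedness: str = "two", alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test of x vs y.

    Uses exact enumeration when n1 + n2 <= 12 with no ties, otherwise the
    normal approximation with midranks, tie correction and continuity
    correction. ``alternative`` follows scipy ("two-sided", "greater", "less")
    and refers to x relative to y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if sidedness == "two":
        alternative = "two-sided"
    elif sidedness == "one" and alternative == "two-sided":
        alternative = "greater"
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        sidedness="two" if alternative == "two-sided" else "one",
        n1=int(x.size),
        n2=int(y.size),
        note=method,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1, monotone in p."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def fisher_r_to_z_compare(
    r1: float,
    n1: int,
    r2: float,
    n2: int,
    sidedness: str = "one",
    dependent_r: float | None = None,
) -> TestResult:
    """Compare two Pearson correlations via Fisher's r-to-z transformation.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); one-sided p is
    P(Z > z), i.e. the alternative is r1 > r2. Independent-samples formula
    by default; pass ``dependent_r`` (the correlation between the two
    predictors, measured on the same n1 == n2 sample sharing one variable)
    to apply Steiger's dependent-correlations correction instead.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 in both samples")
    if dependent_r is not None:
        if n1 != n2:
            raise ValueError("dependent correlations require a shared sample")
        rm2 = ((r1 + r2) / 2) ** 2
        cov = (
            dependent_r * (1 - 2 * rm2)
            - 0.5 * rm2 * (1 - 2 * rm2 - dependent_r**2)
        ) / (1 - rm2) ** 2
        z = (np.arctanh(r1) - np.arctanh(r2)) * np.sqrt((n1 - 3) / (2 - 2 * cov))
    else:
        z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    if sidedness == "one":
        p = float(sps.norm.sf(z))
    else:
        p = float(2 * sps.norm.sf(abs(z)))
    return TestResult(statistic=float(z), p=p, sidedness=sidedness, n1=n1, n2=n2)


def bonferroni(pvals, m: int = 6) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p), default m=6."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * np.asarray(pvals, dtype=float))
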