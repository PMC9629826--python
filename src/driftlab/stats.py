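"""Statistical machinery for condition contrasts.

Thin, explicit wrappers around standard routines: a two-sample
proportions Z-test (pooled-variance form), Benjamini-Hochberg FDR
adjustment, and the rank-sum / paired-t contrasts used to compare
conditions, with results collected in a tidy form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["PropZ", "ContrastResult", "two_proportion_ztest", "bh_adjust",
           "contrast"]


@dataclass(frozen=True)
class PropZ:
    """Two-sample proportions Z-test on pooled variance.

    Z = (p1 - p2) / SE with SE = sqrt(p*(1-p*)(1/n1 + 1/n2)) and p* the
    count-weighted pooled proportion.  The p-value is two-sided normal.
    """

    p1: float
    p2: float
    n1: int
    n2: int
    pooled: float
    se: float
    z: float
    pvalue: float


def two_proportion_ztest(p1: float, n1: int, p2: float, n2: int) -> PropZ:
    """Test whether two observed proportions share one binomial rate."""
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion is degenerate (0 or 1); "
                         "Z is undefined")
    se = float(np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)))
    z = (p1 - p2) / se
    pvalue = float(2.0 * sps.norm.sf(abs(z)))
    return PropZ(p1=p1, p2=p2, n1=n1, n2=n2, pooled=pooled, se=se,
                 z=float(z), pvalue=pvalue)


def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the size of the comparison family; when it exceeds the
    number of supplied p-values (comparisons counted but not listed)
    the family is padded with p = 1 entries, which leaves the supplied
    values' ranks unchanged.
    """
    p = np.atleast_1d(np.asarray(pvalues, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m cannot be smaller than the number "
                         "of p-values")
    padded = np.concatenate([p, np.ones(m - p.size)])
    _, adj, _, _ = multipletests(padded, method="fdr_bh")
    return adj[: p.size]


@dataclass(frozen=True)
class ContrastResult:
    """A single condition contrast in tidy form."""

    test: str
    statistic: float
    n1: int
    n2: int
    pvalue: float
    note: str = ""


def contrast(a, b, test: str = "rank-sum") -> ContrastResult:
    """Compare two condition samples.

    ``"rank-sum"``: Wilcoxon rank-sum (Mann-Whitney), two-sided, exact
    for small samples; the reported statistic is the classic rank-sum
    W (rank total of the first sample).  ``"paired-t"``: two-sided
    paired t-test; identical pairs make t undefined and are reported as
    no difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if test == "rank-sum":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        w = float(res.statistic + a.size * (a.size + 1) / 2.0)
        return ContrastResult(test="rank-sum", statistic=w, n1=a.size,
                              n2=b.size, pvalue=float(res.pvalue))
    if test == "paired-t":
        if a.size != b.size:
            raise ValueError("paired test requires equal-length samples")
        if np.allclose(a, b):
            return ContrastResult(test="paired-t", statistic=float("nan"),
                                  n1=a.size, n2=b.size, pvalue=1.0,
                                  note="identical pairs; t undefined, "
                                       "reported as no difference")
        res = sps.ttest_rel(a, b)
        return ContrastResult(test="paired-t", statistic=float(res.statistic),
                              n1=a.size, n2=b.size, pvalue=float(res.pvalue))
    raise ValueError(f"unknown test {test!r}")
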