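"""Shared statistical primitives: rank tests, Fisher tables, FDR, ECDF."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

# Exact Mann-Whitney null distributions are used for small, tie-free samples;
# larger or tied samples fall back to the normal approximation with tie
# correction (and continuity correction), which is the conventional regime.
EXACT_TOTAL_MAX = 20


def rank_test(
    x, y, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test of `x` against `y`.

    Returns (U statistic of x, p-value). Exact when there are no ties and
    n1 + n2 <= EXACT_TOTAL_MAX, otherwise normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank test requires non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size + y.size <= EXACT_TOTAL_MAX:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_2x2(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table [[a, b], [c, d]].

    Returns (odds ratio, p). The odds ratio is the sample odds ratio
    (a*d)/(b*c), infinite when b*c == 0 and a*d > 0, nan for the empty table.
    """
    (a, b), (c, d) = table
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if b * c == 0:
        odds = np.nan if a * d == 0 else np.inf
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def ecdf_points(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of a sample as (sorted x, F(x)) pairs."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        return x, x
    f = np.arange(1, x.size + 1) / x.size
    return x, f
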