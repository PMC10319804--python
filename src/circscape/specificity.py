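"""Cohort-specific circRNA detection via tandem rank tests.

A circRNA is cohort-specific when its CPM distribution in the focal cohort
is higher than in each of two independent control cohorts: two one-sided
Mann-Whitney tests are run in tandem, Benjamini-Hochberg adjusted across
features separately per test, and a feature passes when both adjusted
values fall below alpha. Each feature additionally carries a combined
p-value, the plain sum of its two unadjusted p-values (may exceed 1;
reported as-is, used for ranking only).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .stats import bh_adjust, rank_test


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample column."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return counts / totals * 1e6


def sum_isoforms(counts: pd.DataFrame, feature_map: dict[str, str]) -> pd.DataFrame:
    """Sum isoform rows to feature (gene) level; unmapped rows are dropped."""
    groups = pd.Series({i: feature_map.get(i) for i in counts.index})
    kept = counts.loc[groups.dropna().index]
    return kept.groupby(groups.dropna()).sum()


def select_top_expressed(cpm: pd.DataFrame, n: int = 500) -> list[str]:
    """Top-n features by mean across samples of per-sample CPM.

    Ties break lexicographically on the feature id, so the ranking is
    stable across runs.
    """
    means = cpm.mean(axis=1)
    order = sorted(means.index, key=lambda i: (-means[i], str(i)))
    return order[:n]


def tandem_specificity_test(
    cohort_cpm: pd.DataFrame,
    control1_cpm: pd.DataFrame,
    control2_cpm: pd.DataFrame,
    prevalence: float = 0.30,
    min_cpm: float = 1.0,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Tandem one-sided rank tests of the focal cohort against two controls.

    Features must reach >= min_cpm in at least ceil(prevalence * n_cohort)
    cohort samples to be tested. Returns a table with per-test p and BH-q
    values, the combined p (sum of the two p-values) and the pass flag
    (both q < alpha). Features absent from a matrix count as all-zero.
    """
    if control1_cpm.shape[1] == 0 or control2_cpm.shape[1] == 0:
        raise ValueError("control cohorts must be non-empty")
    if cohort_cpm.shape[1] == 0:
        raise ValueError("focal cohort must be non-empty")
    universe = sorted(
        set(cohort_cpm.index) | set(control1_cpm.index) | set(control2_cpm.index)
    )
    coh = cohort_cpm.reindex(universe).fillna(0.0)
    c1 = control1_cpm.reindex(universe).fillna(0.0)
    c2 = control2_cpm.reindex(universe).fillna(0.0)

    need = math.ceil(prevalence * coh.shape[1])
    prevalent = (coh >= min_cpm).sum(axis=1) >= need
    tested = [f for f in universe if prevalent[f]]

    rows = []
    for f in tested:
        x = coh.loc[f].to_numpy(dtype=float)
        _, p1 = rank_test(x, c1.loc[f].to_numpy(dtype=float), alternative="greater")
        _, p2 = rank_test(x, c2.loc[f].to_numpy(dtype=float), alternative="greater")
        rows.append({"circ_id": f, "p_vs_tumors": p1, "p_vs_normal": p2})
    result = pd.DataFrame(rows, columns=["circ_id", "p_vs_tumors", "p_vs_normal"])
    if len(result) > 0:
        result["q_vs_tumors"] = bh_adjust(result["p_vs_tumors"].to_numpy())
        result["q_vs_normal"] = bh_adjust(result["p_vs_normal"].to_numpy())
        result["combined_p"] = result["p_vs_tumors"] + result["p_vs_normal"]
        result["passed"] = (result["q_vs_tumors"] < alpha) & (
            result["q_vs_normal"] < alpha
        )
    else:
        for col in ["q_vs_tumors", "q_vs_normal", "combined_p"]:
            result[col] = np.nan
        result["passed"] = pd.Series(dtype=bool)
    return result.sort_values("combined_p").reset_index(drop=True)
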