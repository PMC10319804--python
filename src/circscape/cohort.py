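"""Cohort-level statistics.

Includes the proliferative index (median log2 TPM of a proliferation
signature), the clustering conventions used for circRNA expression heatmaps
(proportion-normalized, z-scored, Manhattan/Canberra distances), RBP-circRNA
Spearman correlation clustering, gene-count-based median-of-ratios size
factors (computed from gene counts and applied to circRNA counts so that a
global shift in circRNA output is not normalized away), and the
percentile-group differential comparison with a chi-square direction test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist

from .stats import bh_adjust, rank_test


# ------------------------------------------------------------ proliferation

def proliferative_index(
    tpm: pd.DataFrame, signature_genes: list[str]
) -> tuple[pd.Series, pd.Series]:
    """Per-sample proliferative index and a 2-cluster high/low split.

    PI = median over signature genes of log2(TPM + 1). Samples are
    hierarchically clustered on the 1-D PI (Euclidean, complete linkage)
    and the tree cut at two clusters, labeled 'high'/'low' by mean PI.
    A degenerate split (all samples identical) labels everything 'low'.
    """
    present = [g for g in signature_genes if g in tpm.index]
    missing = [g for g in signature_genes if g not in tpm.index]
    if not present:
        raise ValueError("no signature gene present in the TPM matrix")
    if missing:
        print(f"note: {len(missing)} signature genes absent from matrix")
    pi = np.log2(tpm.loc[present] + 1.0).median(axis=0)
    if pi.nunique() == 1:
        labels = pd.Series("low", index=pi.index)
        return pi, labels
    Z = linkage(pi.to_numpy()[:, None], method="complete", metric="euclidean")
    cut = cut_tree(Z, n_clusters=2).ravel()
    means = {k: pi[cut == k].mean() for k in (0, 1)}
    high_k = max(means, key=means.get)
    labels = pd.Series(np.where(cut == high_k, "high", "low"), index=pi.index)
    return pi, labels


# --------------------------------------------------------------- clustering

@dataclass
class ClusterResult:
    sample_linkage: np.ndarray
    feature_linkage: np.ndarray | None
    sample_labels: pd.Series
    zscores: pd.DataFrame
    excluded_features: list[str]


def cluster_samples_by_circ(counts: pd.DataFrame, k: int = 3) -> ClusterResult:
    """Heatmap-convention clustering of samples by circRNA expression.

    Each sample is divided by its total read sum, features are z-scored
    across samples (zero-variance features excluded), then samples cluster
    on Manhattan distance and features on Canberra distance, both with
    complete linkage. Sample labels come from cutting the sample tree at k.
    """
    if counts.shape[1] < 3:
        raise ValueError("need at least three samples to cluster")
    totals = counts.sum(axis=0).replace(0, 1)
    prop = counts / totals
    mean = prop.mean(axis=1)
    std = prop.std(axis=1, ddof=1)
    keep = std > 0
    excluded = list(prop.index[~keep])
    z = prop.loc[keep].sub(mean[keep], axis=0).div(std[keep], axis=0)
    sample_Z = linkage(pdist(z.T.to_numpy(), metric="cityblock"), method="complete")
    feature_Z = (
        linkage(pdist(z.to_numpy(), metric="canberra"), method="complete")
        if z.shape[0] >= 2
        else None
    )
    k_eff = min(k, z.shape[1])
    labels = pd.Series(cut_tree(sample_Z, n_clusters=k_eff).ravel(), index=z.columns)
    return ClusterResult(sample_Z, feature_Z, labels, z, excluded)


@dataclass
class RbpCircClusters:
    correlations: pd.DataFrame  # RBPs x circRNAs Spearman rho
    rbp_linkage: np.ndarray
    circ_linkage: np.ndarray
    overlap: pd.DataFrame | None  # normalized cluster-pair counts
    excluded: list[str]


def rbp_circ_cluster(
    rbp_expr: pd.DataFrame,
    circ_expr: pd.DataFrame,
    k_rbp: int = 2,
    k_circ: int = 2,
) -> RbpCircClusters:
    """Spearman correlation of RBP and circRNA expression, clustered.

    Correlations use average ranks for ties; rows/columns with constant
    expression are excluded. Both axes cluster on Euclidean distance of the
    correlation vectors with complete linkage; cluster-pair counts are
    normalized by (|RBP cluster| x |circ cluster|).
    """
    common = [s for s in rbp_expr.columns if s in circ_expr.columns]
    if len(common) < 3:
        raise ValueError("matrices must share at least three samples")
    r = rbp_expr[common]
    c = circ_expr[common]
    excluded = list(r.index[r.std(axis=1) == 0]) + list(c.index[c.std(axis=1) == 0])
    r = r.loc[r.std(axis=1) > 0]
    c = c.loc[c.std(axis=1) > 0]
    r_ranks = r.rank(axis=1)
    c_ranks = c.rank(axis=1)
    rho = np.corrcoef(r_ranks.to_numpy(), c_ranks.to_numpy())[
        : len(r_ranks), len(r_ranks):
    ]
    corr = pd.DataFrame(rho, index=r.index, columns=c.index)
    rbp_Z = (
        linkage(pdist(corr.to_numpy(), metric="euclidean"), method="complete")
        if corr.shape[0] >= 2
        else None
    )
    circ_Z = (
        linkage(pdist(corr.T.to_numpy(), metric="euclidean"), method="complete")
        if corr.shape[1] >= 2
        else None
    )
    overlap = None
    if (
        rbp_Z is not None
        and circ_Z is not None
        and corr.shape[0] >= k_rbp
        and corr.shape[1] >= k_circ
    ):
        rl = cut_tree(rbp_Z, n_clusters=k_rbp).ravel()
        cl = cut_tree(circ_Z, n_clusters=k_circ).ravel()
        # raw count = positively correlated (rbp, circ) pairs in the cluster
        # pair, normalized by |RBP cluster| x |circ cluster|
        grid = np.zeros((k_rbp, k_circ))
        mat = corr.to_numpy()
        for i in range(k_rbp):
            for j in range(k_circ):
                n_r = int((rl == i).sum())
                n_c = int((cl == j).sum())
                if n_r == 0 or n_c == 0:
                    continue
                raw = int((mat[np.ix_(rl == i, cl == j)] > 0).sum())
                grid[i, j] = raw / (n_r * n_c)
        overlap = pd.DataFrame(
            grid,
            index=[f"rbp_{i}" for i in range(k_rbp)],
            columns=[f"circ_{j}" for j in range(k_circ)],
        )
        overlap.attrs["cluster_sizes"] = {
            "rbp": [int((rl == i).sum()) for i in range(k_rbp)],
            "circ": [int((cl == j).sum()) for j in range(k_circ)],
        }
    return RbpCircClusters(corr, rbp_Z, circ_Z, overlap, excluded)


# ------------------------------------------------------------- size factors

def gene_size_factors(gene_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors from the gene count matrix.

    Reference = per-gene geometric mean across samples over genes with no
    zero count; each sample's factor is the median of count/reference over
    those genes. Intended to be applied to circRNA counts, so a global
    change in circRNA output is not normalized away.
    """
    mat = gene_counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene with nonzero counts in every sample")
    sub = mat[nonzero]
    ref = np.exp(np.mean(np.log(sub), axis=1))  # per-gene geometric mean
    factors = np.median(sub / ref[:, None], axis=0)
    return pd.Series(factors, index=gene_counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return counts / factors


# --------------------------------------------------- percentile comparisons

def percentile_groups(
    expression: pd.Series, hi: float = 80, lo: float = 20
) -> tuple[list[str], list[str]]:
    """Samples strictly above the hi-th / strictly below the lo-th percentile.

    Percentiles use linear interpolation between order statistics.
    """
    if hi <= lo:
        raise ValueError("hi percentile must exceed lo percentile")
    hi_v = float(np.percentile(expression, hi))
    lo_v = float(np.percentile(expression, lo))
    high = list(expression.index[expression > hi_v])
    low = list(expression.index[expression < lo_v])
    return high, low


@dataclass
class PercentileComparison:
    table: pd.DataFrame  # feature, p, q, direction
    n_up: int
    n_down: int
    chi2_p: float
    high_samples: list[str]
    low_samples: list[str]


def percentile_group_compare(
    expression: pd.Series,
    features: pd.DataFrame,
    size_factors: pd.Series | None = None,
    hi: float = 80,
    lo: float = 20,
    fdr: float = 0.05,
    min_total_reads: int = 5,
) -> PercentileComparison:
    """Differential comparison between percentile-defined sample groups.

    Features with fewer than `min_total_reads` summed reads are dropped;
    per-feature two-sided rank tests on size-factor-normalized counts are
    BH-adjusted at `fdr`; the balance of significant up vs down calls is
    tested against a 50:50 null with a chi-square test (NaN when nothing is
    significant).
    """
    high, low = percentile_groups(expression, hi, lo)
    if not high or not low:
        raise ValueError("a percentile group is empty")
    norm = features if size_factors is None else normalize(features, size_factors)
    total = features.sum(axis=1)
    norm = norm.loc[total >= min_total_reads]
    rows = []
    for feat, row in norm.iterrows():
        x = row[high].to_numpy(dtype=float)
        y = row[low].to_numpy(dtype=float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0
        else:
            _, p = rank_test(x, y, alternative="two-sided")
        direction = "up" if np.median(x) > np.median(y) else "down"
        rows.append({"feature": feat, "p_value": p, "direction": direction})
    table = pd.DataFrame(rows, columns=["feature", "p_value", "direction"])
    if len(table) > 0:
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
        table["significant"] = table["q_value"] < fdr
    else:
        table["q_value"] = []
        table["significant"] = []
    sig = table[table.get("significant", pd.Series(dtype=bool)) == True]  # noqa: E712
    n_up = int((sig["direction"] == "up").sum()) if len(sig) else 0
    n_down = int((sig["direction"] == "down").sum()) if len(sig) else 0
    if n_up + n_down > 0:
        chi2_p = float(sps.chisquare([n_up, n_down]).pvalue)
    else:
        chi2_p = float("nan")
    return PercentileComparison(table, n_up, n_down, chi2_p, high, low)
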