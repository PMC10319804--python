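"""Circular-to-linear expression ratios and dispersion statistics.

The circ:mRNA ratio of a gene in a sample is the back-splice expression
averaged over the gene's circRNA isoforms divided by the mean linear
junction expression averaged the same way; genes without linear expression
carry no ratio. Group distributions of pooled gene x sample ratios are
compared with a two-sided Mann-Whitney test and exported as ECDFs.

Dispersion is quantified by the Fano factor (variance / mean of counts
across samples, n-1 variance). Constitutive (Poisson) expression has Fano
factor 1; tight regulation pushes it below 1, bursty expression above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ecdf_points, rank_test


def circ_linear_ratio(
    summary: pd.DataFrame, use_external: bool = False
) -> pd.DataFrame:
    """Per-gene per-sample ratio records from a bsj/linear summary table.

    `summary` must have columns circ_id, gene_id, sample, bsj,
    linear_all_mean (and linear_external_mean). Isoform expression is
    averaged within gene before forming the ratio; the ratio is NaN where
    linear expression is zero.
    """
    lin_col = "linear_external_mean" if use_external else "linear_all_mean"
    grouped = (
        summary.groupby(["gene_id", "sample"], sort=True)
        .agg(circ_expr=("bsj", "mean"), linear_expr=(lin_col, "mean"))
        .reset_index()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = grouped["circ_expr"] / grouped["linear_expr"]
    grouped["ratio"] = ratio.where(grouped["linear_expr"] > 0)
    return grouped


@dataclass
class RatioComparison:
    p_value: float
    statistic: float
    direction: str  # which group has the smaller median ratio
    medians: dict[str, float]
    ecdfs: dict[str, tuple[np.ndarray, np.ndarray]]


def compare_ratio_distributions(
    ratios: pd.DataFrame,
    groups: dict[str, str],
    group_a: str | None = None,
    group_b: str | None = None,
) -> RatioComparison:
    """Two-sided rank comparison of pooled ratio distributions between groups."""
    df = ratios.dropna(subset=["ratio"]).copy()
    df["group"] = df["sample"].map(groups)
    labels = sorted(df["group"].dropna().unique())
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValueError(f"need exactly two groups, got {labels}")
        group_a, group_b = labels
    xa = df.loc[df["group"] == group_a, "ratio"].to_numpy()
    xb = df.loc[df["group"] == group_b, "ratio"].to_numpy()
    if xa.size == 0 or xb.size == 0:
        raise ValueError("a group has zero ratio records")
    stat, p = rank_test(xa, xb, alternative="two-sided")
    med = {group_a: float(np.median(xa)), group_b: float(np.median(xb))}
    direction = min(med, key=med.get)
    return RatioComparison(
        p_value=p,
        statistic=stat,
        direction=direction,
        medians=med,
        ecdfs={group_a: ecdf_points(xa), group_b: ecdf_points(xb)},
    )


def call_productive_genes(
    circ_isoforms: dict[str, int],
    mrna_isoforms: dict[str, int],
    threshold: float = 1.2,
) -> tuple[pd.DataFrame, list[str]]:
    """Flag genes whose circ-to-mRNA isoform-count ratio exceeds `threshold`.

    Returns (table, excluded_genes) where excluded genes have zero expressed
    mRNA isoforms. The comparison is strict (> threshold).
    """
    rows, excluded = [], []
    for gene in sorted(set(circ_isoforms) | set(mrna_isoforms)):
        n_c = int(circ_isoforms.get(gene, 0))
        n_m = int(mrna_isoforms.get(gene, 0))
        if n_m == 0:
            excluded.append(gene)
            continue
        ratio = n_c / n_m
        rows.append(
            {
                "gene_id": gene,
                "n_circ_isoforms": n_c,
                "n_mrna_isoforms": n_m,
                "ratio": ratio,
                "productive": ratio > threshold,
            }
        )
    return (
        pd.DataFrame(
            rows,
            columns=["gene_id", "n_circ_isoforms", "n_mrna_isoforms", "ratio", "productive"],
        ),
        excluded,
    )


def count_expressed_isoforms(
    bsj_counts: pd.DataFrame,
    circ_gene: dict[str, str],
    tx_tpm: pd.DataFrame,
    tx_gene: dict[str, str],
    min_tpm: float = 1.0,
) -> tuple[dict[str, int], dict[str, int]]:
    """Expressed-isoform tallies for productive-gene calling.

    A circ isoform is expressed with >= 1 back-splice read in >= 1 sample;
    an mRNA isoform with TPM >= min_tpm in >= 1 sample.
    """
    circ_tally: dict[str, int] = {}
    for circ_id, row in bsj_counts.iterrows():
        if (row >= 1).any() and circ_id in circ_gene:
            g = circ_gene[circ_id]
            circ_tally[g] = circ_tally.get(g, 0) + 1
    mrna_tally: dict[str, int] = {}
    for tid, row in tx_tpm.iterrows():
        if (row >= min_tpm).any() and tid in tx_gene:
            g = tx_gene[tid]
            mrna_tally[g] = mrna_tally.get(g, 0) + 1
    return circ_tally, mrna_tally


def fano_factor(counts: pd.DataFrame) -> pd.Series:
    """Per-row Fano factor: sample variance (n-1) over sample mean.

    NaN where the mean is zero. Requires >= 2 samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("Fano factor requires at least two samples")
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    fano = var / mean
    return fano.where(mean > 0)


@dataclass
class FanoComparison:
    table: pd.DataFrame  # feature_id, kind, fano
    p_value: float
    statistic: float


def fano_by_feature(
    isoform_counts: pd.DataFrame, isoform_feature: dict[str, str]
) -> pd.Series:
    """Isoform Fano factors averaged within feature (gene)."""
    fano = fano_factor(isoform_counts)
    feat = pd.Series({i: isoform_feature.get(i) for i in isoform_counts.index})
    df = pd.DataFrame({"fano": fano, "feature": feat}).dropna()
    return df.groupby("feature")["fano"].mean()


def compare_fano(
    circ_counts: pd.DataFrame,
    linear_counts: pd.DataFrame,
    circ_feature: dict[str, str],
    linear_feature: dict[str, str],
) -> FanoComparison:
    """Circular vs linear dispersion: per-feature averaged Fano factors
    compared with a two-sided rank test."""
    f_c = fano_by_feature(circ_counts, circ_feature)
    f_l = fano_by_feature(linear_counts, linear_feature)
    stat, p = rank_test(f_c.to_numpy(), f_l.to_numpy(), alternative="two-sided")
    table = pd.concat(
        [
            pd.DataFrame({"feature_id": f_c.index, "kind": "circ", "fano": f_c.to_numpy()}),
            pd.DataFrame({"feature_id": f_l.index, "kind": "linear", "fano": f_l.to_numpy()}),
        ],
        ignore_index=True,
    )
    return FanoComparison(table=table, p_value=p, statistic=stat)
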