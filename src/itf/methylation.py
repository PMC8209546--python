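"""Differential-methylation arm: normalization, probe filtering, per-CpG
rank-sum testing with BH FDR, genomic context distribution, the
promoter-CGI signature, and sample clustering / group concordance."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr, rankdata

from .stats import benjamini_hochberg, rank_sum_test

PROMOTER_REGIONS = ("TSS1500", "TSS200")


class SchemaError(ValueError):
    pass


class InvalidGroupingError(ValueError):
    pass


class InsufficientSignatureError(ValueError):
    pass


def dm_proportion(n_dm: int, n_valid: int, decimals: int = 1) -> float:
    """Percentage of valid CpGs called differentially methylated."""
    if n_valid <= 0:
        raise ValueError("n_valid must be positive")
    return round(100.0 * n_dm / n_valid, decimals)


def quantile_normalize(beta: pd.DataFrame) -> pd.DataFrame:
    """Classic across-sample quantile normalization.

    Each column's sorted values are replaced by the rank-wise mean across
    columns; ties receive the mean of their rank span (average ranks).
    """
    if beta.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    values = beta.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise SchemaError("non-numeric or non-finite entries")
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, len(ref) + 1), ref)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


def filter_probes(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    annotation: pd.DataFrame,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Drop SNP-flagged probes, then probes failing detection (p > p_max)
    in any sample.  Returns the retained beta matrix."""
    if beta.shape != detp.shape or not beta.index.equals(detp.index):
        raise SchemaError("beta and detection-p matrices do not align")
    annot = annotation.set_index("cpg_id")
    missing = beta.index.difference(annot.index)
    if len(missing):
        raise SchemaError(f"annotation missing for {len(missing)} probes")
    snp = annot.loc[beta.index, "snp_flag"].astype(bool).to_numpy()
    fail = (detp.to_numpy() > p_max).any(axis=1)
    keep = ~snp & ~fail
    return beta.loc[keep]


def split_groups(columns, prefix_a: str = "A", prefix_b: str = "B"):
    """Column index arrays for a two-group design encoded in sample names."""
    cols = list(columns)
    a = np.array([i for i, c in enumerate(cols) if str(c).startswith(prefix_a)])
    b = np.array([i for i, c in enumerate(cols) if str(c).startswith(prefix_b)])
    if len(a) == 0 or len(b) == 0:
        raise InvalidGroupingError("both groups must be present in the columns")
    return a, b


def dmcpg_test(beta: pd.DataFrame, groups: pd.Series | dict, fdr: float = 0.05) -> pd.DataFrame:
    """Per-CpG two-sided rank-sum test with BH adjustment.

    ``groups`` maps sample id -> group label (exactly two labels).  The
    returned table has one row per CpG: delta_beta (mean A - mean B),
    wilcoxon_p, fdr_q, significant.
    """
    groups = pd.Series(groups)
    labels = sorted(pd.unique(groups.loc[beta.columns]))
    if len(labels) != 2:
        raise InvalidGroupingError(f"expected exactly 2 group labels, got {labels}")
    ga = np.flatnonzero((groups.loc[beta.columns] == labels[0]).to_numpy())
    gb = np.flatnonzero((groups.loc[beta.columns] == labels[1]).to_numpy())
    if len(ga) < 2 or len(gb) < 2:
        raise InvalidGroupingError("need >= 2 samples per group")
    values = beta.to_numpy(dtype=float)
    pvals = np.empty(values.shape[0])
    for i in range(values.shape[0]):
        _, pvals[i] = rank_sum_test(values[i, ga], values[i, gb])
    qvals = benjamini_hochberg(pvals)
    delta = values[:, ga].mean(axis=1) - values[:, gb].mean(axis=1)
    return pd.DataFrame(
        {
            "cpg_id": beta.index,
            "delta_beta": delta,
            "wilcoxon_p": pvals,
            "fdr_q": qvals,
            "significant": qvals < fdr,
        }
    ).reset_index(drop=True)


def genomic_distribution(dm: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of significant CpGs over CpG context x gene
    region; marginal percentages each sum to 100."""
    if dm.empty:
        raise ValueError("empty DMCpG table")
    annot = annotation.set_index("cpg_id")
    sig = dm.loc[dm["significant"], "cpg_id"]
    sub = annot.loc[annot.index.intersection(sig)]
    table = pd.crosstab(sub["cpg_context"], sub["gene_region"])
    total = int(table.to_numpy().sum())
    out = table.stack().rename("count").reset_index()
    out["pct_of_total"] = 100.0 * out["count"] / total if total else 0.0
    return out


def promoter_cgi_signature(
    dm: pd.DataFrame,
    annotation: pd.DataFrame,
    promoter_regions=PROMOTER_REGIONS,
) -> tuple[list[str], dict]:
    """Significant CpGs in CpG islands of promoters, plus their gene map.

    Returns (cpg_ids, {cpg_id: gene_symbol}) with empty symbols dropped
    from the map (but not from the CpG set).
    """
    annot = annotation.set_index("cpg_id")
    sig = dm.loc[dm["significant"], "cpg_id"]
    sub = annot.loc[annot.index.intersection(sig)]
    picked = sub.loc[
        (sub["cpg_context"] == "island") & (sub["gene_region"].isin(promoter_regions))
    ]
    cpgs = sorted(picked.index)
    gene_map = {c: g for c, g in picked["gene_symbol"].items() if g}
    return cpgs, gene_map


def cluster_samples(
    beta: pd.DataFrame,
    cpg_ids,
    n_clusters: int = 2,
    method: str = "average",
    metric: str = "euclidean",
):
    """Hierarchical clustering of samples on a CpG subset.

    Returns (sample order, linkage matrix, flat cluster labels).
    """
    cpg_ids = [c for c in cpg_ids if c in beta.index]
    if len(cpg_ids) < 2:
        raise InsufficientSignatureError("need >= 2 CpGs to cluster")
    sub = beta.loc[cpg_ids].to_numpy(dtype=float).T  # samples x cpgs
    z = linkage(sub, method=method, metric=metric)
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    from scipy.cluster.hierarchy import leaves_list

    order = [beta.columns[i] for i in leaves_list(z)]
    return order, z, labels


def group_mean_concordance(beta: pd.DataFrame, groups: pd.Series | dict) -> float:
    """R^2 (squared Pearson) of per-CpG group means over all CpGs."""
    groups = pd.Series(groups)
    labels = sorted(pd.unique(groups.loc[beta.columns]))
    if len(labels) != 2:
        raise InvalidGroupingError("expected exactly 2 groups")
    a_cols = [c for c in beta.columns if groups[c] == labels[0]]
    b_cols = [c for c in beta.columns if groups[c] == labels[1]]
    ma = beta[a_cols].mean(axis=1)
    mb = beta[b_cols].mean(axis=1)
    r, _ = pearsonr(ma, mb)
    return float(r**2)
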