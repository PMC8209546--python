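"""Methylation-expression integration producing the epigenetic signature:
promoter-CGI genes whose methylation direction opposes their differential
expression (hypermethylated & down, hypomethylated & up)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .methylation import InsufficientSignatureError, cluster_samples
from .stats import benjamini_hochberg, rank_sum_test


def surrogate_de(counts: pd.DataFrame, groups: pd.Series | dict, fdr: float = 0.05) -> pd.DataFrame:
    """Plumbing stand-in for a full DE engine.

    Median-of-ratios library-size normalization, per-gene two-sided
    rank-sum test on log2(normalized + 1), BH adjustment; log2fc is the
    difference of group means on that log scale (group A minus group B).
    """
    groups = pd.Series(groups)
    labels = sorted(pd.unique(groups.loc[counts.columns]))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {labels}")
    ga = np.flatnonzero((groups.loc[counts.columns] == labels[0]).to_numpy())
    gb = np.flatnonzero((groups.loc[counts.columns] == labels[1]).to_numpy())
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need >= 2 samples per group")

    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat).mean(axis=1)  # -inf for genes with any zero
    usable = np.isfinite(log_geo)
    if usable.any():
        ratios = np.log(mat[usable]) - log_geo[usable, None]
        size = np.exp(np.median(ratios, axis=0))
    else:
        size = mat.sum(axis=0) / max(1.0, np.median(mat.sum(axis=0)))
    norm = mat / size
    log_norm = np.log2(norm + 1.0)

    pvals = np.empty(mat.shape[0])
    for i in range(mat.shape[0]):
        if np.ptp(log_norm[i]) == 0:
            pvals[i] = 1.0
        else:
            _, pvals[i] = rank_sum_test(log_norm[i, ga], log_norm[i, gb])
    qvals = benjamini_hochberg(pvals)
    log2fc = log_norm[:, ga].mean(axis=1) - log_norm[:, gb].mean(axis=1)
    return pd.DataFrame(
        {
            "gene_symbol": counts.index,
            "log2fc": log2fc,
            "p": pvals,
            "adj_p": qvals,
        }
    ).reset_index(drop=True)


def gene_methylation_direction(
    cpg_ids,
    dm: pd.DataFrame,
    gene_map: dict,
    min_delta: float = 0.05,
) -> dict:
    """Per-gene signed methylation direction.

    Direction is the sign of the mean delta_beta over the gene's signature
    CpGs; genes whose mean magnitude falls below ``min_delta`` are dropped.
    """
    dm_idx = dm.set_index("cpg_id")
    missing = [c for c in cpg_ids if c in gene_map and c not in dm_idx.index]
    if missing:
        raise KeyError(f"DM table missing CpGs: {missing[:5]}")
    per_gene: dict[str, list[float]] = {}
    for c in cpg_ids:
        g = gene_map.get(c)
        if not g:
            continue
        per_gene.setdefault(g, []).append(float(dm_idx.loc[c, "delta_beta"]))
    directions = {}
    for g, deltas in per_gene.items():
        mean = float(np.mean(deltas))
        if abs(mean) < min_delta:
            continue
        directions[g] = 1 if mean > 0 else -1
    return directions


@dataclass
class EpigeneticSignature:
    hyper_down: list[str] = field(default_factory=list)
    hypo_up: list[str] = field(default_factory=list)
    cpgs: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return sorted(self.hyper_down) + sorted(self.hypo_up)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene_symbol": g, "class": "hyper_down"} for g in sorted(self.hyper_down)]
        rows += [{"gene_symbol": g, "class": "hypo_up"} for g in sorted(self.hypo_up)]
        return pd.DataFrame(rows, columns=["gene_symbol", "class"])


def build_signature(
    directions: dict,
    de: pd.DataFrame,
    gene_map: dict | None = None,
    q_max: float = 0.05,
) -> EpigeneticSignature:
    """Intersect methylation directions with opposing DE directions."""
    sig_de = de.loc[de["adj_p"] < q_max].set_index("gene_symbol")
    hyper_down, hypo_up = [], []
    for g, d in directions.items():
        if g not in sig_de.index:
            continue
        lfc = float(sig_de.loc[g, "log2fc"])
        if d > 0 and lfc < 0:
            hyper_down.append(g)
        elif d < 0 and lfc > 0:
            hypo_up.append(g)
    member = set(hyper_down) | set(hypo_up)
    cpgs = sorted(c for c, g in (gene_map or {}).items() if g in member)
    return EpigeneticSignature(
        hyper_down=sorted(hyper_down), hypo_up=sorted(hypo_up), cpgs=cpgs
    )


def signature_separation(
    beta: pd.DataFrame,
    signature: EpigeneticSignature,
    groups: pd.Series | dict,
) -> float:
    """ARI of 2-way hierarchical clustering on the signature CpGs against
    the true group labels."""
    if not signature.cpgs:
        raise InsufficientSignatureError("empty signature")
    _, _, labels = cluster_samples(beta, signature.cpgs, n_clusters=2)
    groups = pd.Series(groups)
    truth = groups.loc[beta.columns].to_numpy()
    return float(adjusted_rand_score(truth, labels))
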