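"""Synthetic array-style methylation dataset with planted differential CpGs.

Baseline per-CpG means follow a bimodal Beta mixture (the classic two-hump
beta-value landscape).  A planted fraction of CpGs is shifted between the
two sample groups; a configurable subset of genes gets consistent
island-promoter CpG blocks so the downstream signature stage has a known
recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fibers import InvalidSpecError

CPG_CONTEXTS = ("island", "shore", "shelf", "open_sea")
GENE_REGIONS = ("TSS1500", "TSS200", "5UTR", "1stExon", "body", "3UTR", "IGR")

DEFAULT_CONTEXT_PROPS = {"island": 0.30, "shore": 0.25, "shelf": 0.10, "open_sea": 0.35}
DEFAULT_REGION_PROPS = {
    "TSS1500": 0.15,
    "TSS200": 0.10,
    "5UTR": 0.10,
    "1stExon": 0.05,
    "body": 0.35,
    "3UTR": 0.05,
    "IGR": 0.20,
}


@dataclass(frozen=True)
class MethylSpec:
    n_cpgs: int = 5000
    n_samples_a: int = 10
    n_samples_b: int = 10
    dm_fraction: float = 0.035
    delta_beta: float = 0.2  # planted group-mean beta difference
    precision: float = 150.0  # Beta-noise concentration
    context_props: dict = field(default_factory=lambda: dict(DEFAULT_CONTEXT_PROPS))
    region_props: dict = field(default_factory=lambda: dict(DEFAULT_REGION_PROPS))
    snp_fraction: float = 0.02
    detp_fail_fraction: float = 0.002
    cpgs_per_gene_max: int = 4
    n_signature_genes: int = 30  # genes given coherent island-promoter DM blocks
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_a < 2 or self.n_samples_b < 2:
            raise InvalidSpecError("need >= 2 samples per group")
        for name in ("dm_fraction", "snp_fraction", "detp_fail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"{name} must lie in [0, 1]")
        if self.n_cpgs <= 0 or self.precision <= 0:
            raise InvalidSpecError("n_cpgs and precision must be positive")
        for props in (self.context_props, self.region_props):
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise InvalidSpecError("context/region proportions must sum to 1")


@dataclass
class MethylTruth:
    """Planted ground truth: one row per planted DMCpG, direction = sign of
    mean beta(group A) - mean beta(group B)."""

    table: pd.DataFrame  # cpg_id, direction
    gene_directions: dict  # island-promoter gene -> +1/-1 (coherent blocks)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.table["cpg_id"])


def generate_methylation_dataset(
    spec: MethylSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, MethylTruth]:
    """Returns (beta, detection_p, annotation, truth).

    beta/detection_p: CpG x sample DataFrames; annotation: one row per CpG
    with genomic context and a SNP flag.  Deterministic for a fixed spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cpgs
    cpg_ids = np.array([f"cg{i:07d}" for i in range(1, n + 1)])
    samples = [f"A{i + 1:02d}" for i in range(spec.n_samples_a)] + [
        f"B{i + 1:02d}" for i in range(spec.n_samples_b)
    ]

    # --- annotation -------------------------------------------------------
    ctx = rng.choice(list(spec.context_props), size=n, p=list(spec.context_props.values()))
    region = rng.choice(list(spec.region_props), size=n, p=list(spec.region_props.values()))
    gene = np.array([""] * n, dtype=object)
    genic = np.flatnonzero(region != "IGR")
    gi, gene_counter = 0, 0
    while gi < len(genic):
        gene_counter += 1
        size = int(rng.integers(1, spec.cpgs_per_gene_max + 1))
        for j in genic[gi : gi + size]:
            gene[j] = f"GENE{gene_counter:05d}"
        gi += size
    snp = rng.random(n) < spec.snp_fraction

    # coherent island-promoter blocks for the signature genes: pick genes
    # with >= 2 CpGs and overwrite their annotation
    n_dm = int(round(spec.dm_fraction * n))
    gene_sizes = pd.Series(gene[gene != ""]).value_counts()
    candidates = [g for g in gene_sizes.index[gene_sizes >= 2]]
    rng.shuffle(candidates)
    n_sig = min(spec.n_signature_genes, len(candidates))
    sig_genes = candidates[:n_sig]
    gene_directions: dict[str, int] = {}
    planted_idx: list[int] = []
    directions: list[int] = []
    for k, g in enumerate(sig_genes):
        idx = np.flatnonzero(gene == g)
        room = n_dm - len(planted_idx)
        if room <= 0:
            break
        d = -1 if k % 2 == 0 else 1  # hypo-first: default couplings need 11 hypo vs 9 hyper
        gene_directions[g] = d
        ctx[idx] = "island"
        region[idx] = rng.choice(["TSS1500", "TSS200"], size=len(idx))
        idx = idx[:room]  # stay inside the planted-DM budget
        planted_idx.extend(idx.tolist())
        directions.extend([d] * len(idx))

    # scatter the remaining planted CpGs over unplanted probes
    remaining = n_dm - len(planted_idx)
    if remaining > 0:
        free = np.setdiff1d(np.arange(n), np.array(planted_idx, dtype=int))
        extra = rng.choice(free, size=remaining, replace=False)
        extra_dir = rng.choice([-1, 1], size=remaining)
        planted_idx.extend(extra.tolist())
        directions.extend(extra_dir.tolist())

    chrom = np.array([f"chr{(i % 22) + 1}" for i in range(n)])
    pos = np.arange(1, n + 1) * 1000
    annotation = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "chrom": chrom,
            "pos": pos,
            "cpg_context": ctx,
            "gene_region": region,
            "gene_symbol": gene,
            "snp_flag": snp,
        }
    )

    # --- beta values ------------------------------------------------------
    # bimodal baseline; planted CpGs get mid-range baselines so the
    # symmetric shift stays inside (0, 1)
    low = rng.beta(2.0, 10.0, size=n)
    high = rng.beta(10.0, 2.0, size=n)
    mu = np.where(rng.random(n) < 0.5, low, high)
    planted = np.array(planted_idx, dtype=int)
    dir_arr = np.array(directions, dtype=int)
    if spec.delta_beta == 0:
        dir_arr = np.zeros_like(dir_arr)
    mu[planted] = rng.uniform(0.3, 0.7, size=len(planted))

    half = spec.delta_beta / 2.0
    mu_a = mu.copy()
    mu_b = mu.copy()
    mu_a[planted] = np.clip(mu[planted] + dir_arr * half, 0.02, 0.98)
    mu_b[planted] = np.clip(mu[planted] - dir_arr * half, 0.02, 0.98)

    kappa = spec.precision
    beta = np.empty((n, len(samples)))
    for j in range(spec.n_samples_a):
        beta[:, j] = rng.beta(mu_a * kappa, (1 - mu_a) * kappa)
    for j in range(spec.n_samples_b):
        beta[:, spec.n_samples_a + j] = rng.beta(mu_b * kappa, (1 - mu_b) * kappa)
    beta_df = pd.DataFrame(beta, index=cpg_ids, columns=samples)
    beta_df.index.name = "cpg_id"

    # signature-gene CpGs are exempt from QC-failure injection so the
    # planted recovery target survives probe filtering
    sig_cpg_idx = np.flatnonzero(np.isin(gene, list(gene_directions)))
    snp[sig_cpg_idx] = False
    annotation.loc[sig_cpg_idx, "snp_flag"] = False

    detp = rng.uniform(0.0, 0.005, size=beta.shape)
    fails = rng.random(beta.shape) < spec.detp_fail_fraction
    fails[sig_cpg_idx, :] = False
    detp[fails] = rng.uniform(0.011, 0.5, size=int(fails.sum()))
    detp_df = pd.DataFrame(detp, index=cpg_ids, columns=samples)
    detp_df.index.name = "cpg_id"

    truth_table = pd.DataFrame(
        {"cpg_id": cpg_ids[planted], "direction": dir_arr}
    ).reset_index(drop=True)
    truth = MethylTruth(table=truth_table, gene_directions=dict(gene_directions))
    if spec.delta_beta == 0:
        truth.gene_directions = {}
    return beta_df, detp_df, annotation, truth
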