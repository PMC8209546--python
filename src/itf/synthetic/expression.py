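"""Synthetic negative-binomial count matrix with planted DE genes.

A configurable number of planted DE genes is anti-coupled to the planted
methylation directions (methylation up -> expression down and vice versa),
so the integration stage has an exact recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fibers import InvalidSpecError
from .methyl import MethylTruth


@dataclass(frozen=True)
class ExprSpec:
    n_genes: int = 1392
    n_samples_a: int = 10
    n_samples_b: int = 10
    nb_dispersion: float = 0.1
    log2fc: float = 2.0  # planted |log2 fold change|, group A vs B
    n_coupled_hyper_down: int = 9
    n_coupled_hypo_up: int = 11
    n_extra_up: int = 40  # planted DE genes without methylation coupling
    n_extra_down: int = 30
    mean_log_expression: float = 5.5  # natural-log scale of baseline means
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_a < 2 or self.n_samples_b < 2:
            raise InvalidSpecError("need >= 2 samples per group")
        if self.n_genes <= 0:
            raise InvalidSpecError("n_genes must be positive")
        if self.nb_dispersion <= 0:
            raise InvalidSpecError("nb_dispersion must be positive")
        for name in ("n_coupled_hyper_down", "n_coupled_hypo_up", "n_extra_up", "n_extra_down"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_expression_dataset(
    spec: ExprSpec, methyl_truth: MethylTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (counts, truth).

    counts: gene x sample integer DataFrame.  truth: one row per planted
    DE gene with the planted log2fc sign and, for coupled genes, the
    opposing methylation direction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    hyper = sorted(g for g, d in methyl_truth.gene_directions.items() if d > 0)
    hypo = sorted(g for g, d in methyl_truth.gene_directions.items() if d < 0)
    if spec.log2fc != 0:
        if spec.n_coupled_hyper_down > len(hyper):
            raise InvalidSpecError(
                f"requested {spec.n_coupled_hyper_down} hyper-down couplings but only "
                f"{len(hyper)} hypermethylated genes are available"
            )
        if spec.n_coupled_hypo_up > len(hypo):
            raise InvalidSpecError(
                f"requested {spec.n_coupled_hypo_up} hypo-up couplings but only "
                f"{len(hypo)} hypomethylated genes are available"
            )
    coupled_down = hyper[: spec.n_coupled_hyper_down] if spec.log2fc != 0 else []
    coupled_up = hypo[: spec.n_coupled_hypo_up] if spec.log2fc != 0 else []

    meth_genes = set(methyl_truth.gene_directions)
    genes = sorted(meth_genes)
    extra_needed = spec.n_genes - len(genes)
    if extra_needed < 0:
        raise InvalidSpecError("n_genes smaller than the methylation gene universe")
    genes += [f"XGENE{i:05d}" for i in range(1, extra_needed + 1)]
    genes = np.array(genes)

    free = [g for g in genes if g not in meth_genes]
    rng.shuffle(free)
    n_extra = spec.n_extra_up + spec.n_extra_down
    if spec.log2fc != 0 and n_extra > len(free):
        raise InvalidSpecError("not enough uncoupled genes for extra DE genes")
    extra_up = free[: spec.n_extra_up] if spec.log2fc != 0 else []
    extra_down = free[spec.n_extra_up : n_extra] if spec.log2fc != 0 else []

    lfc = pd.Series(0.0, index=genes)
    for g in coupled_up + list(extra_up):
        lfc[g] = spec.log2fc
    for g in coupled_down + list(extra_down):
        lfc[g] = -spec.log2fc

    base = np.exp(rng.normal(spec.mean_log_expression, 1.0, size=len(genes)))
    mean_a = base * 2.0 ** (lfc.values / 2.0)
    mean_b = base * 2.0 ** (-lfc.values / 2.0)

    samples = [f"EA{i + 1:02d}" for i in range(spec.n_samples_a)] + [
        f"EB{i + 1:02d}" for i in range(spec.n_samples_b)
    ]
    counts = np.empty((len(genes), len(samples)), dtype=np.int64)
    for j in range(spec.n_samples_a):
        counts[:, j] = _nb_draw(rng, mean_a, spec.nb_dispersion)
    for j in range(spec.n_samples_b):
        counts[:, spec.n_samples_a + j] = _nb_draw(rng, mean_b, spec.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    counts_df.index.name = "gene_symbol"

    rows = []
    for g in genes[lfc.values != 0]:
        coupled = g in coupled_up or g in coupled_down
        rows.append(
            {
                "gene_symbol": g,
                "log2fc_planted": float(lfc[g]),
                "coupled": coupled,
                "meth_direction": methyl_truth.gene_directions.get(g, 0) if coupled else 0,
            }
        )
    truth = pd.DataFrame(rows, columns=["gene_symbol", "log2fc_planted", "coupled", "meth_direction"])
    return counts_df, truth
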