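"""Reference benchmarks run by the acceptance suite and the CLI demo.

Each benchmark regenerates its synthetic inputs from a seed, runs the
relevant pipeline stages, and reports recovery metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import integration as integ
from . import methylation as me
from . import segmentation as seg
from .synthetic import (
    ExprSpec,
    FiberImageSpec,
    MethylSpec,
    generate_expression_dataset,
    generate_methylation_dataset,
)


def default_benchmark_spec(seed: int, **overrides) -> FiberImageSpec:
    """One 1-mm^2 tile at scanner resolution with the benchmark defaults."""
    n_px = round(1000.0 / 0.46)
    params = dict(width_px=n_px, height_px=n_px, n_fibers=80,
                  mean_fiber_width=5.0, noise_sd=8.0, seed=seed)
    params.update(overrides)
    return FiberImageSpec(**params)


def _image_features(image, resolution):
    od = seg.optical_density(image)
    enh = seg.enhance_fibers(od, resolution=resolution)
    return seg.pixel_features(od, enh, resolution=resolution)


def segmentation_benchmark(
    n_images: int = 20,
    seed: int = 42,
    n_train: int | None = None,
    n_sample: int = 100_000,
    test_subsample: int | None = None,
    **spec_overrides,
) -> dict:
    """Train the logistic pixel model on the first half of a fixed-seed
    image series and report pooled pixel-wise ROC AUC on the second half.

    Seeds are ``seed, seed+1, ..., seed+n_images-1``.  ``test_subsample``
    optionally caps pooled test pixels per image (deterministic stride)
    to bound memory on very large runs.
    """
    if n_train is None:
        n_train = n_images // 2
    specs = [default_benchmark_spec(seed + i, **spec_overrides) for i in range(n_images)]
    resolution = specs[0].resolution

    # balanced per-image pixel subsample keeps peak memory to one image
    per_image = max(1000, n_sample // max(n_train, 1))
    feats_list, labels_list = [], []
    for i, s in enumerate(specs[:n_train]):
        from .synthetic import generate_fiber_image

        im = generate_fiber_image(s)
        f = _image_features(im.image, resolution).reshape(-1, len(seg.FEATURE_NAMES))
        y = im.truth_mask.reshape(-1)
        rng = np.random.default_rng(seed * 1000 + i)
        pos = np.flatnonzero(y)
        neg = np.flatnonzero(~y)
        take = np.concatenate(
            [
                rng.choice(pos, size=min(per_image // 2, len(pos)), replace=False),
                rng.choice(neg, size=min(per_image // 2, len(neg)), replace=False),
            ]
        )
        feats_list.append(f[take])
        labels_list.append(y[take])
    features = np.concatenate(feats_list)
    labels = np.concatenate(labels_list)
    model = seg.fit_pixel_logit(features, labels, n_sample=n_sample, seed=seed)
    del feats_list, labels_list, features, labels

    scores, truth = [], []
    for s in specs[n_train:]:
        from .synthetic import generate_fiber_image

        im = generate_fiber_image(s)
        f = _image_features(im.image, resolution)
        p = seg.probability_map(model, f).astype(np.float32).ravel()
        t = im.truth_mask.ravel()
        if test_subsample and p.size > test_subsample:
            step = p.size // test_subsample
            p, t = p[::step], t[::step]
        scores.append(p)
        truth.append(t)
    scores = np.concatenate(scores)
    truth = np.concatenate(truth)
    auc = seg.roc_auc(scores, truth)
    return {
        "auc": float(auc),
        "n_pixels": int(scores.size),
        "n_train_images": n_train,
        "n_test_images": n_images - n_train,
        "model": model,
    }


def signature_recovery_benchmark(seed: int = 7) -> dict:
    """Full synthetic methylation + expression run at default coupling.

    Returns the recovered signature, the planted coupled-gene truth, and
    the clustering ARI.
    """
    beta, detp, annot, mtruth = generate_methylation_dataset(MethylSpec(seed=seed))
    counts, etruth = generate_expression_dataset(ExprSpec(seed=seed), mtruth)

    filtered = me.filter_probes(beta, detp, annot)
    groups = pd.Series({c: ("A" if str(c).startswith("A") else "B") for c in beta.columns})
    dm = me.dmcpg_test(filtered, groups)
    sig_cpgs, gene_map = me.promoter_cgi_signature(dm, annot)
    directions = integ.gene_methylation_direction(sig_cpgs, dm, gene_map)

    egroups = pd.Series(
        {c: ("A" if str(c).startswith("EA") else "B") for c in counts.columns}
    )
    de = integ.surrogate_de(counts, egroups)
    signature = integ.build_signature(directions, de, gene_map)
    ari = integ.signature_separation(filtered, signature, groups)

    planted = set(etruth.loc[etruth["coupled"], "gene_symbol"])
    return {
        "signature": signature,
        "n_genes": len(signature.genes),
        "n_hyper_down": len(signature.hyper_down),
        "n_hypo_up": len(signature.hypo_up),
        "planted_genes": planted,
        "exact_recovery": set(signature.genes) == planted,
        "ari": float(ari),
        "n_signature_cpgs": len(signature.cpgs),
        "dm_table": dm,
    }
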