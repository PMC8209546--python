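"""End-to-end orchestration: simulate -> segment -> morphometry -> compare
-> immune -> methyl -> integrate, with a run manifest covering all I/O."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import integration as integ
from . import methylation as me
from . import segmentation as seg
from .io import (
    save_fiber_image,
    sha256_of,
    write_json,
    write_mask,
    write_matrix_tsv,
)
from .morphometry import measure_fibers, summarize_roi, tissue_area
from .roi import build_comparison_table
from .synthetic import (
    CellFieldSpec,
    ExprSpec,
    FiberImageSpec,
    MethylSpec,
    generate_cell_table,
    generate_expression_dataset,
    generate_fiber_image,
    generate_methylation_dataset,
)

log = logging.getLogger("itf")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: dict, out_dir: Path | None = None) -> dict:
    """Run all stages in dependency order; returns the manifest dict.

    Every output file is listed in ``manifest.json`` with its sha256, so a
    rerun with the same config can be verified bit-for-bit.
    """
    out = Path(out_dir if out_dir is not None else config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {"seed": seed, "stages": {}, "files": {}}

    def record(stage: str, *paths: Path):
        for p in paths:
            manifest["files"][str(Path(p).relative_to(out))] = sha256_of(p)
            manifest["stages"].setdefault(stage, []).append(str(Path(p).relative_to(out)))

    current = "simulate"
    try:
        t0 = time.time()
        log.info("stage simulate")
        fib_cfg = dict(config["simulate"]["fibers"])
        n_images = int(fib_cfg.pop("n_images"))
        images = []
        for i in range(n_images):
            spec = FiberImageSpec(seed=seed + i, **fib_cfg)
            im = generate_fiber_image(spec)
            images.append((spec, im))
            paths = save_fiber_image(out / "simulate", im, f"image_{i:02d}")
            record("simulate", *paths.values())

        cell_cfg = dict(config["simulate"]["cells"])
        cell_cfg["roi_size_mm"] = tuple(cell_cfg["roi_size_mm"])
        cells = generate_cell_table(CellFieldSpec(seed=seed, **cell_cfg))
        cells_path = out / "simulate" / "cells.csv"
        cells.to_csv(cells_path, index=False)
        record("simulate", cells_path)

        mspec = MethylSpec(seed=seed, **config["simulate"]["methyl"])
        beta, detp, annot, mtruth = generate_methylation_dataset(mspec)
        espec = ExprSpec(seed=seed, **config["simulate"]["expression"])
        counts, etruth = generate_expression_dataset(espec, mtruth)
        for name, df in (("beta", beta), ("detp", detp), ("counts", counts)):
            p = out / "simulate" / f"{name}.tsv"
            write_matrix_tsv(p, df)
            record("simulate", p)
        for name, df in (("annotation", annot), ("methyl_truth", mtruth.table), ("expr_truth", etruth)):
            p = out / "simulate" / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            record("simulate", p)

        current = "segment"
        log.info("stage segment")
        seg_cfg = config["segment"]
        spec0, im0 = images[0]
        od0 = seg.optical_density(im0.image)
        enh0 = seg.enhance_fibers(od0, n_iter=seg_cfg["n_iter"], resolution=spec0.resolution)
        feats0 = seg.pixel_features(od0, enh0, resolution=spec0.resolution)
        model = seg.fit_pixel_logit(
            feats0, im0.truth_mask, n_sample=seg_cfg["n_sample"], seed=seed
        )
        model_path = out / "segment" / "model.json"
        model_path.parent.mkdir(parents=True, exist_ok=True)
        model_path.write_text(model.to_json())
        record("segment", model_path)

        fiber_sets, od_maps, metrics = [], [], {}
        for i, (spec, im) in enumerate(images):
            od = seg.optical_density(im.image)
            enh = seg.enhance_fibers(od, n_iter=seg_cfg["n_iter"], resolution=spec.resolution)
            feats = seg.pixel_features(od, enh, resolution=spec.resolution)
            prob = seg.probability_map(model, feats)
            fibers = seg.segment_fibers(
                prob, seg_cfg["threshold"], seg_cfg["min_area_um2"], spec.resolution
            )
            fiber_sets.append(fibers)
            od_maps.append(od)
            metrics[f"image_{i:02d}"] = {
                "auc": seg.roc_auc(prob, im.truth_mask),
                "n_fibers": fibers.n_fibers,
                "n_planted": len(im.truth_table),
            }
            mask_path = out / "segment" / f"image_{i:02d}_labels.png"
            write_mask(mask_path, fibers.labels > 0)
            record("segment", mask_path)
        metrics_path = out / "segment" / "metrics.json"
        write_json(metrics_path, metrics)
        record("segment", metrics_path)

        current = "morphometry"
        log.info("stage morphometry")
        morpho_dir = out / "morphometry"
        morpho_dir.mkdir(parents=True, exist_ok=True)
        summaries = []
        for i, ((spec, im), fibers, od) in enumerate(zip(images, fiber_sets, od_maps)):
            morphs = measure_fibers(fibers)
            # fixed white reference: estimated I0 would put hole-free tissue at OD ~ 0
            od_white = seg.optical_density(im.image, i0=np.array([255.0, 255.0, 255.0]))
            core = tissue_area(od_white, config["morphometry"]["od_min"], spec.resolution)
            summary = summarize_roi(fibers, morphs, core)
            p = morpho_dir / f"image_{i:02d}_fibers.csv"
            morphs.to_csv(p, index=False)
            record("morphometry", p)
            summaries.append(
                {
                    "sample": f"image_{i:02d}",
                    "group": "a" if i % 2 == 0 else "b",
                    "density_per_mm2": summary.density_per_mm2,
                    "pct_sa": summary.pct_sa,
                    **summary.parameter_means,
                }
            )
        summary_df = pd.DataFrame(summaries)
        p = morpho_dir / "roi_summaries.csv"
        summary_df.to_csv(p, index=False)
        record("morphometry", p)

        current = "compare"
        log.info("stage compare")
        params = [c for c in summary_df.columns if c not in ("sample", "group")]
        try:
            table = build_comparison_table(
                summary_df,
                params,
                alpha_var=config["compare"]["alpha_var"],
                bh_correct=config["compare"]["bh_correct"],
            )
        except Exception:  # too few demo images for statistics: emit empty table
            table = pd.DataFrame()
        p = out / "compare" / "morphometry_comparisons.csv"
        p.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(p, index=False)
        record("compare", p)

        current = "immune"
        log.info("stage immune")
        from .immune import summarize_cell_table

        w_um = cell_cfg["roi_size_mm"][0] * 1000.0
        h_um = cell_cfg["roi_size_mm"][1] * 1000.0
        rects = {rid: (0.0, 0.0, w_um, h_um) for rid in cells["roi_id"].unique()}
        dens = summarize_cell_table(cells, rects, config["immune"]["margin_um"])
        p = out / "immune" / "densities.csv"
        p.parent.mkdir(parents=True, exist_ok=True)
        dens.to_csv(p, index=False)
        record("immune", p)

        current = "methyl"
        log.info("stage methyl")
        mdir = out / "methyl"
        mdir.mkdir(parents=True, exist_ok=True)
        work = beta
        if config["methyl"]["quantile_normalize"]:
            work = me.quantile_normalize(work)
        filtered = me.filter_probes(work, detp, annot, config["methyl"]["p_max"])
        groups = pd.Series(
            {c: ("A" if str(c).startswith("A") else "B") for c in beta.columns}
        )
        dm = me.dmcpg_test(filtered, groups, fdr=config["methyl"]["fdr"])
        dm.to_csv(mdir / "dmcpg.csv", index=False)
        dist = me.genomic_distribution(dm, annot)
        dist.to_csv(mdir / "genomic_distribution.csv", index=False)
        sig_cpgs, gene_map = me.promoter_cgi_signature(dm, annot)
        pd.DataFrame(
            {"cpg_id": sig_cpgs, "gene_symbol": [gene_map.get(c, "") for c in sig_cpgs]}
        ).to_csv(mdir / "promoter_cgi_signature.csv", index=False)
        order, linkage_z, _ = me.cluster_samples(filtered, sig_cpgs) if len(sig_cpgs) >= 2 else (list(beta.columns), None, None)
        write_json(
            mdir / "clustering.json",
            {
                "sample_order": list(order),
                "linkage": linkage_z.tolist() if linkage_z is not None else [],
                "r2_group_means": me.group_mean_concordance(filtered, groups),
            },
        )
        record("methyl", mdir / "dmcpg.csv", mdir / "genomic_distribution.csv",
               mdir / "promoter_cgi_signature.csv", mdir / "clustering.json")

        current = "integrate"
        log.info("stage integrate")
        idir = out / "integrate"
        idir.mkdir(parents=True, exist_ok=True)
        egroups = pd.Series(
            {c: ("A" if str(c).startswith("EA") else "B") for c in counts.columns}
        )
        de = integ.surrogate_de(counts, egroups)
        de.to_csv(idir / "de.csv", index=False)
        directions = integ.gene_methylation_direction(
            sig_cpgs, dm, gene_map, min_delta=config["integrate"]["min_delta"]
        )
        signature = integ.build_signature(
            directions, de, gene_map, q_max=config["integrate"]["q_max"]
        )
        signature.to_frame().to_csv(idir / "signature.csv", index=False)
        try:
            ari = integ.signature_separation(filtered, signature, groups)
        except me.InsufficientSignatureError:
            ari = float("nan")
        write_json(
            idir / "signature.json",
            {
                "hyper_down": signature.hyper_down,
                "hypo_up": signature.hypo_up,
                "n_cpgs": len(signature.cpgs),
                "ari": None if np.isnan(ari) else ari,
            },
        )
        record("integrate", idir / "de.csv", idir / "signature.csv", idir / "signature.json")

        manifest["elapsed_s"] = round(time.time() - t0, 2)
    except Exception as exc:  # partial outputs are retained on disk
        manifest_path = out / "manifest.json"
        write_json(manifest_path, manifest)
        raise StageError(current, exc) from exc

    manifest_path = out / "manifest.json"
    write_json(manifest_path, manifest)
    return manifest
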