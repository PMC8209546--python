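"""Synthetic phenotyped cell tables (marked point patterns).

Emulates the tabular output of a nuclear-detection + phenotype classifier:
one row per cell with coordinates in um, a phenotype label, and the ROI it
belongs to.  Densities are per ROI category; points are Poisson or Thomas
(clustered) processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fibers import InvalidSpecError

PHENOTYPES = ("CD68", "CD3", "CD8", "CD20", "CK", "other")
ROI_CATEGORIES = ("tumor", "myometrium", "itf")


@dataclass(frozen=True)
class CellFieldSpec:
    """Densities are cells/mm^2 keyed as ``densities[category][phenotype]``."""

    roi_size_mm: tuple[float, float] = (1.0, 1.0)
    densities: dict = field(
        default_factory=lambda: {
            cat: {p: 100.0 for p in PHENOTYPES} for cat in ROI_CATEGORIES
        }
    )
    clustering: float = 0.0  # 0 = Poisson; >0 = Thomas process, offspring per parent
    cluster_sigma_um: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.roi_size_mm[0] <= 0 or self.roi_size_mm[1] <= 0:
            raise InvalidSpecError("ROI size must be positive")
        for cat, dens in self.densities.items():
            if cat not in ROI_CATEGORIES:
                raise InvalidSpecError(f"unknown ROI category {cat!r}")
            for ph, d in dens.items():
                if ph not in PHENOTYPES:
                    raise InvalidSpecError(f"unknown phenotype {ph!r}")
                if d < 0:
                    raise InvalidSpecError("densities must be >= 0")
        if self.clustering < 0:
            raise InvalidSpecError("clustering must be >= 0")


def _scatter(rng, n: int, w_um: float, h_um: float, clustering: float, sigma: float):
    """n points in [0,w]x[0,h]; Thomas-process clustered when requested."""
    if clustering <= 0 or n == 0:
        return rng.uniform(0, w_um, n), rng.uniform(0, h_um, n)
    n_parents = max(1, int(round(n / clustering)))
    px = rng.uniform(0, w_um, n_parents)
    py = rng.uniform(0, h_um, n_parents)
    parent = rng.integers(0, n_parents, n)
    x = np.mod(px[parent] + rng.normal(0, sigma, n), w_um)
    y = np.mod(py[parent] + rng.normal(0, sigma, n), h_um)
    return x, y


def generate_cell_table(spec: CellFieldSpec, rois: dict[str, str] | None = None) -> pd.DataFrame:
    """One DataFrame of cells for the given ROIs.

    ``rois`` maps roi_id -> category; defaults to one ROI per category.
    Counts per (ROI, phenotype) are Poisson(density x area).
    """
    spec.validate()
    if rois is None:
        rois = {f"roi_{cat}": cat for cat in spec.densities}
    rng = np.random.default_rng(spec.seed)
    w_um = spec.roi_size_mm[0] * 1000.0
    h_um = spec.roi_size_mm[1] * 1000.0
    area_mm2 = spec.roi_size_mm[0] * spec.roi_size_mm[1]
    rows = []
    for roi_id, cat in rois.items():
        if cat not in spec.densities:
            raise InvalidSpecError(f"no densities for ROI category {cat!r}")
        for ph in PHENOTYPES:
            dens = spec.densities[cat].get(ph, 0.0)
            n = rng.poisson(dens * area_mm2)
            x, y = _scatter(rng, n, w_um, h_um, spec.clustering, spec.cluster_sigma_um)
            for xi, yi in zip(x, y):
                rows.append((float(xi), float(yi), ph, roi_id, cat))
    return pd.DataFrame(rows, columns=["x", "y", "phenotype", "roi_id", "roi_category"])
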