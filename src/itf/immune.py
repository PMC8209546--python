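"""Immune-cell density summaries from phenotyped cell tables."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .roi import build_comparison_table
from .synthetic.cells import PHENOTYPES

IMMUNE_PHENOTYPES = ("CD68", "CD3", "CD8", "CD20")


class DegenerateAreaError(ValueError):
    pass


class SchemaError(ValueError):
    pass


def exclude_border_cells(
    cells: pd.DataFrame,
    roi_rect: tuple[float, float, float, float],
    margin_um: float = 20.0,
) -> tuple[pd.DataFrame, float]:
    """Drop cells within ``margin_um`` of any ROI edge.

    Returns the filtered table and the effective area (mm^2) to use as the
    density denominator.
    """
    if margin_um < 0:
        raise ValueError("margin must be >= 0")
    x0, y0, w, h = roi_rect
    if 2 * margin_um >= min(w, h):
        raise DegenerateAreaError("margin leaves no interior area")
    keep = (
        (cells["x"] >= x0 + margin_um)
        & (cells["x"] <= x0 + w - margin_um)
        & (cells["y"] >= y0 + margin_um)
        & (cells["y"] <= y0 + h - margin_um)
    )
    effective_mm2 = (w - 2 * margin_um) * (h - 2 * margin_um) * 1e-6
    return cells.loc[keep].reset_index(drop=True), effective_mm2


@dataclass
class CellDensitySummary:
    roi_id: str
    densities: dict  # phenotype -> cells/mm^2
    total_cells: float  # density of all cells
    total_immune: float  # CD68 + CD3 + CD8 + CD20 densities

    def as_row(self) -> dict:
        return {
            "roi_id": self.roi_id,
            **{p: self.densities[p] for p in PHENOTYPES},
            "total_cells": self.total_cells,
            "total_immune": self.total_immune,
        }


def immune_summary(cells: pd.DataFrame, roi_id: str, effective_area_mm2: float) -> CellDensitySummary:
    """Per-phenotype densities (cells/mm^2) plus the immune aggregate."""
    if effective_area_mm2 <= 0:
        raise DegenerateAreaError("effective area must be positive")
    unknown = set(cells["phenotype"].unique()) - set(PHENOTYPES)
    if unknown:
        raise SchemaError(f"unknown phenotypes: {sorted(unknown)}")
    counts = cells["phenotype"].value_counts()
    densities = {p: float(counts.get(p, 0)) / effective_area_mm2 for p in PHENOTYPES}
    total_cells = float(len(cells)) / effective_area_mm2
    total_immune = sum(densities[p] for p in IMMUNE_PHENOTYPES)
    return CellDensitySummary(
        roi_id=roi_id,
        densities=densities,
        total_cells=total_cells,
        total_immune=total_immune,
    )


def summarize_cell_table(
    cells: pd.DataFrame,
    roi_rects: dict,
    margin_um: float = 20.0,
) -> pd.DataFrame:
    """One density row per ROI; ``roi_rects`` maps roi_id -> (x, y, w, h) um."""
    rows = []
    for roi_id, rect in roi_rects.items():
        sub = cells.loc[cells["roi_id"] == roi_id]
        kept, area = exclude_border_cells(sub, rect, margin_um)
        rows.append(immune_summary(kept, roi_id, area).as_row())
    return pd.DataFrame(rows)


def compare_immune_groups(
    summaries: pd.DataFrame,
    group_col: str = "group",
    parameters=(*PHENOTYPES, "total_cells", "total_immune"),
    contrasts=None,
) -> pd.DataFrame:
    """Delegates to the ROI group-comparison machinery over per-sample
    mean densities."""
    return build_comparison_table(summaries, parameters, group_col=group_col, contrasts=contrasts)
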