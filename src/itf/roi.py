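"""ROI categorization and two-group comparison statistics.

ROIs are rectangles in slide coordinates (um, origin top-left, y down)
classified against pathologist annotation polygons; group comparisons use
the variance-ratio (Fisher-Snedecor) test to choose between pooled and
Welch t flavors, with significance stars at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import box as shapely_box
from shapely.ops import unary_union

from .stats import benjamini_hochberg, f_variance_test, stars


class AnnotationMissingError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class ROISpec:
    id: str
    rectangle: tuple[float, float, float, float]  # x, y, w, h in um
    size_class: str  # large_5x4mm | small_1mm2
    category: str  # tumor | myometrium | itf | whole | uncategorized
    tumor_fraction: float


def categorize_roi(
    rect: tuple[float, float, float, float],
    tumor_polygons,
    myometrium_polygons,
    roi_id: str = "roi",
    size_class: str = "small_1mm2",
) -> ROISpec:
    """Category from the tumor-area fraction of the rectangle:
    >= 0.95 tumor, <= 0.05 myometrium, 0.4-0.6 the invasion front."""
    if not tumor_polygons and not myometrium_polygons:
        raise AnnotationMissingError("no annotation polygons supplied")
    x, y, w, h = rect
    r = shapely_box(x, y, x + w, y + h)
    tumor_union = unary_union(list(tumor_polygons)) if tumor_polygons else None
    frac = (r.intersection(tumor_union).area / r.area) if tumor_union is not None else 0.0
    if frac >= 0.95:
        category = "tumor"
    elif frac <= 0.05:
        category = "myometrium"
    elif 0.4 <= frac <= 0.6:
        category = "itf"
    else:
        category = "uncategorized"
    return ROISpec(
        id=roi_id,
        rectangle=tuple(float(v) for v in rect),
        size_class=size_class,
        category=category,
        tumor_fraction=float(frac),
    )


@dataclass
class GroupComparison:
    parameter: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    f_stat: float
    f_p: float
    t_stat: float
    t_p: float
    variance_equal: bool
    stars: str


def compare_groups(values_a, values_b, parameter: str = "", alpha_var: float = 0.05) -> GroupComparison:
    """F-test-gated two-sample t-test (pooled when variances look equal,
    Welch otherwise), two-sided throughout."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >= 2 values per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InsufficientDataError("non-finite values in input")
    f_stat, f_p = f_variance_test(a, b)
    equal_var = f_p >= alpha_var
    if np.ptp(np.concatenate([a, b])) == 0:
        t_stat, t_p = 0.0, 1.0
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t_stat, t_p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(t_stat):
            t_stat, t_p = 0.0, 1.0
    return GroupComparison(
        parameter=parameter,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=len(a),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=len(b),
        f_stat=f_stat,
        f_p=f_p,
        t_stat=t_stat,
        t_p=t_p,
        variance_equal=bool(equal_var),
        stars=stars(t_p),
    )


def build_comparison_table(
    summaries: pd.DataFrame,
    parameters,
    group_col: str = "group",
    contrasts=None,
    alpha_var: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One GroupComparison row per parameter per contrast.

    ``summaries`` holds one row per sample (per-sample means) with a group
    column; ``contrasts`` is a list of (group_a, group_b) pairs, defaulting
    to all ordered pairs of observed groups.  Rows with insufficient data
    report NaN statistics instead of aborting the table.
    """
    groups = list(pd.unique(summaries[group_col]))
    if contrasts is None:
        contrasts = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    rows = []
    for ga, gb in contrasts:
        va = summaries.loc[summaries[group_col] == ga]
        vb = summaries.loc[summaries[group_col] == gb]
        for p in parameters:
            base = {"contrast": f"{ga}_vs_{gb}", "parameter": p}
            try:
                c = compare_groups(va[p].to_numpy(), vb[p].to_numpy(), parameter=p,
                                   alpha_var=alpha_var)
            except InsufficientDataError as exc:
                rows.append({**base, "error": str(exc)})
                continue
            d = c.__dict__.copy()
            d.pop("parameter")
            rows.append({**base, **d, "error": ""})
    table = pd.DataFrame(rows)
    if bh_correct and "t_p" in table:
        ok = table["t_p"].notna()
        q = benjamini_hochberg(table.loc[ok, "t_p"].to_numpy())
        table.loc[ok, "t_q"] = q
        table.loc[ok, "stars"] = [stars(v) for v in q]
    return table
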