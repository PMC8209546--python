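"""Per-fiber morphometry and ROI-level fiber summaries.

Thirteen per-fiber parameters (size, shape, skeleton and fractal measures)
plus the two ROI-level ones (fiber density and percent stained area) make
up the fifteen-parameter suite.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import perimeter_crofton, regionprops
from skimage.morphology import closing, convex_hull_image, disk, skeletonize

from .segmentation import FiberSet, ODMap

PER_FIBER_PARAMETERS = (
    "area_um2",
    "perimeter_um",
    "convex_perimeter_um",
    "perimeter_ratio",
    "width_um",
    "height_um",
    "skeleton_length_um",
    "aspect",
    "vertices",
    "fractal_dimension",
    "shape",
    "deformity_um2",
    "solidity",
)


class DegenerateComponentError(ValueError):
    pass


@dataclass
class FiberMorphometry:
    fiber_id: int
    area_um2: float
    perimeter_um: float
    convex_perimeter_um: float
    perimeter_ratio: float
    width_um: float
    height_um: float
    skeleton_length_um: float
    aspect: float
    vertices: int
    fractal_dimension: float
    shape: float
    deformity_um2: float
    solidity: float


def box_counting_dimension(mask: np.ndarray, sizes=(1, 2, 4, 8, 16, 32, 64)) -> float:
    """Least-squares slope of log N(s) against log(1/s) over dyadic box sizes."""
    mask = np.asarray(mask, dtype=bool)
    counts, used = [], []
    for s in sizes:
        if s > max(mask.shape):
            break
        h = int(np.ceil(mask.shape[0] / s)) * s
        w = int(np.ceil(mask.shape[1] / s)) * s
        padded = np.zeros((h, w), dtype=bool)
        padded[: mask.shape[0], : mask.shape[1]] = mask
        blocks = padded.reshape(h // s, s, w // s, s).any(axis=(1, 3))
        n = int(blocks.sum())
        if n == 0:
            return float("nan")
        counts.append(n)
        used.append(s)
    if len(used) < 2:
        return float("nan")
    slope = np.polyfit(np.log(used), np.log(counts), 1)[0]
    return float(-slope)


def _skeleton_vertices(skeleton: np.ndarray, merge_radius_px: int = 3) -> int:
    """Branch points: skeleton pixels with >= 3 skeleton neighbors, merged
    when within the given radius of each other."""
    sk = skeleton.astype(np.uint8)
    neighbor_count = ndi.convolve(sk, np.ones((3, 3), dtype=np.uint8), mode="constant") - sk
    branch = skeleton & (neighbor_count >= 3)
    if not branch.any():
        return 0
    merged = ndi.binary_dilation(branch, structure=disk(merge_radius_px))
    _, n = ndi.label(merged)
    return int(n)


def _prune_spurs(skeleton: np.ndarray, n_iter: int = 4) -> np.ndarray:
    """Iteratively strip endpoint pixels to remove rasterization spurs."""
    sk = skeleton.copy()
    kernel = np.ones((3, 3), dtype=np.uint8)
    for _ in range(n_iter):
        neighbors = ndi.convolve(sk.astype(np.uint8), kernel, mode="constant") - sk
        endpoints = sk & (neighbors <= 1)
        if not endpoints.any():
            break
        sk &= ~endpoints
    return sk if sk.any() else skeleton


def measure_fiber(mask: np.ndarray, resolution: float, fiber_id: int = 0) -> FiberMorphometry:
    """All per-fiber parameters for one connected-component mask."""
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px < 2:
        raise DegenerateComponentError("component too small to measure")
    r = resolution
    area = n_px * r * r
    perim = perimeter_crofton(mask, directions=4) * r
    hull = convex_hull_image(mask)
    convex_perim = perimeter_crofton(hull, directions=4) * r
    hull_area = int(hull.sum()) * r * r
    perimeter_ratio = min(1.0, convex_perim / perim) if perim > 0 else 1.0
    solidity = min(1.0, area / hull_area) if hull_area > 0 else 1.0

    skeleton = skeletonize(mask)  # Zhang-Suen: guaranteed 1 px thick
    dist = ndi.distance_transform_edt(mask)
    # skeleton-end tails extend ~ the local half-width into corners: prune that deep
    prune_depth = int(np.ceil(dist[skeleton].max())) + 2 if skeleton.any() else 4
    pruned = _prune_spurs(skeleton, n_iter=prune_depth)
    sk_px = int(pruned.sum())
    skeleton_length = sk_px * r
    width = 2.0 * float(dist[pruned].mean()) * r if sk_px else 2.0 * r
    props = regionprops(mask.astype(np.uint8))[0]
    height = float(props.feret_diameter_max) * r
    if height < width:  # blob-like: caliper bound
        height = width
    aspect = height / width if width > 0 else float("nan")
    vertices = _skeleton_vertices(pruned)
    fractal = box_counting_dimension(mask)
    shape = perim**2 / (4.0 * np.pi * area)
    deformity = perim**2 - 4.0 * np.pi * area
    return FiberMorphometry(
        fiber_id=fiber_id,
        area_um2=float(area),
        perimeter_um=float(perim),
        convex_perimeter_um=float(convex_perim),
        perimeter_ratio=float(perimeter_ratio),
        width_um=float(width),
        height_um=float(height),
        skeleton_length_um=float(skeleton_length),
        aspect=float(aspect),
        vertices=vertices,
        fractal_dimension=float(fractal),
        shape=float(shape),
        deformity_um2=float(deformity),
        solidity=float(solidity),
    )


def measure_fibers(fibers: FiberSet) -> pd.DataFrame:
    """One row per labeled component."""
    rows = []
    objects = ndi.find_objects(fibers.labels)
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = fibers.labels[sl] == i
        try:
            m = measure_fiber(mask, fibers.resolution, fiber_id=i)
        except DegenerateComponentError:
            continue
        rows.append(asdict(m))
    return pd.DataFrame(rows, columns=["fiber_id", *PER_FIBER_PARAMETERS])


def tissue_area(
    od: ODMap,
    od_min: float = 0.08,
    resolution: float = 0.46,
    closing_um: float = 20.0,
) -> float:
    """Intact-tissue (core) area in mm^2: channel-averaged OD >= od_min after
    a morphological closing that fills pinholes smaller than ``closing_um``."""
    if od_min < 0:
        raise ValueError("od_min must be >= 0")
    mask = od.values >= od_min
    radius = max(1, int(round(closing_um / resolution / 2)))
    mask = closing(mask, disk(radius))
    return float(mask.sum()) * (resolution * 1e-3) ** 2


@dataclass
class ROIFiberSummary:
    total_fibers: int
    core_area_mm2: float
    sum_fiber_area_um2: float
    density_per_mm2: float
    pct_sa: float
    parameter_means: dict


def summarize_roi(fibers: FiberSet, morphs: pd.DataFrame, core_area_mm2: float) -> ROIFiberSummary:
    """ROI totals: density = fibers / core area; %SA = 100 x fiber area / core area."""
    if core_area_mm2 <= 0:
        raise ZeroDivisionError("core area must be positive")
    total = len(morphs)
    sum_area = float(morphs["area_um2"].sum()) if total else 0.0
    density = total / core_area_mm2
    pct_sa = 100.0 * (sum_area * 1e-6) / core_area_mm2
    means = {
        p: (float(morphs[p].mean()) if total else float("nan")) for p in PER_FIBER_PARAMETERS
    }
    return ROIFiberSummary(
        total_fibers=total,
        core_area_mm2=float(core_area_mm2),
        sum_fiber_area_um2=sum_area,
        density_per_mm2=float(density),
        pct_sa=float(pct_sa),
        parameter_means=means,
    )
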