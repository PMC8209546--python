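"""Synthetic silver-stained fiber image generator.

Produces dark curvilinear branching fibers on a pale noisy background with
pixel-level ground truth, so segmentation and morphometry can be tested by
parameter recovery.  Centerlines are cubic-smoothed random walks dilated to
a planted width; branching is Bernoulli per unit length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import CubicSpline
from skimage.draw import line as draw_line


class InvalidSpecError(ValueError):
    """Raised when a generator spec violates its invariants."""


@dataclass(frozen=True)
class FiberImageSpec:
    """Parameters of one synthetic fiber tile."""

    width_px: int = 1024
    height_px: int = 1024
    resolution: float = 0.46  # um per pixel
    n_fibers: int = 80
    mean_fiber_width: float = 5.0  # um
    width_cv: float = 0.2
    curvature: float = 0.25  # step-angle SD, radians
    branch_prob: float = 1.0  # branches per 100 um of centerline
    fiber_intensity_mean: float = 90.0
    background_intensity_mean: float = 200.0
    noise_sd: float = 8.0
    blur_sigma: float = 0.8  # px
    hole_fraction: float = 0.0
    min_length_um: float = 50.0
    max_length_um: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise InvalidSpecError("image dimensions must be positive")
        if self.resolution <= 0:
            raise InvalidSpecError("resolution must be positive")
        if self.n_fibers < 0:
            raise InvalidSpecError("n_fibers must be >= 0")
        if not self.fiber_intensity_mean < self.background_intensity_mean:
            raise InvalidSpecError("fibers must be darker than background")
        for name in ("width_cv", "hole_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"{name} must lie in [0, 1]")
        if self.curvature < 0:
            raise InvalidSpecError("curvature must be >= 0")
        if self.mean_fiber_width <= 0:
            raise InvalidSpecError("mean_fiber_width must be positive")


@dataclass
class SyntheticFiberImage:
    """Rendered tile plus ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) bool, fiber pixels
    tissue_mask: np.ndarray  # (H, W) bool, intact tissue
    truth_table: list[dict] = field(default_factory=list)
    resolution: float = 0.46


def _centerline(rng, spec: FiberImageSpec, start, theta0, length_px) -> np.ndarray:
    """Cubic-smoothed random-walk polyline at ~1 px spacing."""
    step = max(4.0, 8.0)  # coarse waypoint spacing, px
    n_steps = max(2, int(np.ceil(length_px / step)))
    theta = theta0
    pts = [np.asarray(start, dtype=float)]
    for _ in range(n_steps):
        theta += rng.normal(0.0, spec.curvature)
        pts.append(pts[-1] + step * np.array([np.cos(theta), np.sin(theta)]))
    pts = np.array(pts)
    t = np.arange(len(pts))
    cs_r = CubicSpline(t, pts[:, 0])
    cs_c = CubicSpline(t, pts[:, 1])
    tf = np.linspace(0, len(pts) - 1, max(2, int(length_px)))
    return np.column_stack([cs_r(tf), cs_c(tf)])


def _render_fiber(rng, spec: FiberImageSpec, shape, length_scale: float = 1.0):
    """One fiber rendered in its bounding box.

    Returns ``(slices, mask, alpha, record)`` where ``slices`` locate the
    box in the full frame, or None when the fiber falls outside it.
    """
    h, w = shape
    length_um = length_scale * rng.uniform(spec.min_length_um, spec.max_length_um)
    length_px = length_um / spec.resolution
    width_um = max(
        spec.resolution,
        rng.normal(spec.mean_fiber_width, spec.width_cv * spec.mean_fiber_width),
    )
    half_w_px = width_um / spec.resolution / 2.0
    start = np.array([rng.uniform(0, h - 1), rng.uniform(0, w - 1)])
    theta0 = rng.uniform(0, 2 * np.pi)
    polylines = [_centerline(rng, spec, start, theta0, length_px)]
    # Bernoulli branching per ~1 px of centerline
    n_branches = 0
    p_branch_per_px = spec.branch_prob * spec.resolution / 100.0
    if p_branch_per_px > 0:
        main = polylines[0]
        seg_hits = rng.random(len(main)) < p_branch_per_px
        for idx in np.flatnonzero(seg_hits):
            if idx < 2 or idx > len(main) - 3:
                continue
            d = main[idx + 1] - main[idx - 1]
            base_theta = np.arctan2(d[1], d[0])
            side = rng.choice([-1.0, 1.0])
            branch_theta = base_theta + side * rng.uniform(np.pi / 4, np.pi / 3)
            branch_len = rng.uniform(0.25, 0.6) * length_px
            polylines.append(_centerline(rng, spec, main[idx], branch_theta, branch_len))
            n_branches += 1

    pts = np.vstack(polylines)
    pad = int(np.ceil(half_w_px)) + 2
    r0 = max(0, int(np.floor(pts[:, 0].min())) - pad)
    r1 = min(h, int(np.ceil(pts[:, 0].max())) + pad + 1)
    c0 = max(0, int(np.floor(pts[:, 1].min())) - pad)
    c1 = min(w, int(np.ceil(pts[:, 1].max())) + pad + 1)
    if r1 - r0 < 2 or c1 - c0 < 2:
        return None
    box = (r1 - r0, c1 - c0)
    center = np.zeros(box, dtype=bool)
    for poly in polylines:
        local = poly - [r0, c0]
        pix = np.clip(np.round(local).astype(int), [0, 0], [box[0] - 1, box[1] - 1])
        for (a0, b0), (a1, b1) in zip(pix[:-1], pix[1:]):
            rr, cc = draw_line(a0, b0, a1, b1)
            center[rr, cc] = True
    dist = ndi.distance_transform_edt(~center)
    mask = dist <= half_w_px
    alpha = np.clip(half_w_px + 1.0 - dist, 0.0, 1.0)
    record = {
        "width_um": float(width_um),
        "length_um": float(length_um),
        "n_branches": int(n_branches),
    }
    return (slice(r0, r1), slice(c0, c1)), mask, alpha, record


def _carve_holes(rng, spec: FiberImageSpec, shape) -> np.ndarray:
    """Random-ellipse damage mask; True where tissue is intact."""
    tissue = np.ones(shape, dtype=bool)
    target = spec.hole_fraction * tissue.size
    carved = 0
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    while carved < target:
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry = rng.uniform(0.02, 0.08) * h
        rx = rng.uniform(0.02, 0.08) * w
        phi = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(phi) + dx * np.sin(phi)
        v = -dy * np.sin(phi) + dx * np.cos(phi)
        ellipse = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        newly = np.count_nonzero(ellipse & tissue)
        tissue &= ~ellipse
        carved += newly
    return tissue


def generate_fiber_image(spec: FiberImageSpec) -> SyntheticFiberImage:
    """Render one tile; deterministic for a fixed spec (incl. seed).

    Fibers are placed with rejection sampling so that distinct fibers do
    not touch: connected components of the truth mask then correspond
    one-to-one to planted fibers (when ``hole_fraction`` is 0).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height_px, spec.width_px)

    truth = np.zeros(shape, dtype=bool)
    # 3-px keep-out gap keeps 8-connected components separable
    buffer_px = 3
    occupied = np.zeros(shape, dtype=bool)
    alpha_total = np.zeros(shape, dtype=float)
    records: list[dict] = []
    attempts, max_attempts = 0, max(100, spec.n_fibers * 60)
    while len(records) < spec.n_fibers and attempts < max_attempts:
        attempts += 1
        # crowded tiles: progressively shorten candidates so packing succeeds
        length_scale = max(0.25, 1.0 - attempts / max_attempts)
        rendered = _render_fiber(rng, spec, shape, length_scale)
        if rendered is None:
            continue
        sl, mask, alpha, rec = rendered
        if np.any(mask & occupied[sl]):
            continue
        truth[sl] |= mask
        occupied[sl] |= ndi.binary_dilation(mask, iterations=buffer_px)
        alpha_total[sl] = np.maximum(alpha_total[sl], alpha)
        rec["id"] = len(records) + 1
        records.append(rec)

    tissue = (
        _carve_holes(rng, spec, shape) if spec.hole_fraction > 0 else np.ones(shape, dtype=bool)
    )
    truth &= tissue
    alpha_total[~tissue] = 0.0

    background = rng.normal(spec.background_intensity_mean, spec.noise_sd, size=shape)
    img = background.copy()
    fiber_level = rng.normal(spec.fiber_intensity_mean, spec.noise_sd, size=shape)
    img = img * (1.0 - alpha_total) + fiber_level * alpha_total
    img[~tissue] = rng.normal(245.0, 2.0, size=shape)[~tissue]
    if spec.blur_sigma > 0:
        img = ndi.gaussian_filter(img, spec.blur_sigma)
    img8 = np.clip(img, 0, 255).astype(np.uint8)
    rgb = np.stack([img8, img8, img8], axis=-1)

    out = SyntheticFiberImage(
        image=rgb,
        truth_mask=truth,
        tissue_mask=tissue,
        truth_table=records,
        resolution=spec.resolution,
    )
    return out
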