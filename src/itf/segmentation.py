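"""Probabilistic reticular-fiber segmentation.

Pipeline: optical density -> iterative fiber enhancement (median-background
subtraction + multiscale ridge response) -> per-pixel neighborhood features
-> logistic pixel model -> probability map -> threshold + minimum-area
filter -> labeled fibers.  Evaluation is pixel-wise ROC AUC against a
ground-truth mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals, structure_tensor
from skimage.measure import label as cc_label
from skimage.transform import resize
from sklearn.linear_model import LogisticRegression

from .stats import rank_auc

DEFAULT_OD_MAX = 3.0
DEFAULT_FEATURE_WINDOW = 9
DEFAULT_SCALES_UM = (2.5, 4.0)

FEATURE_NAMES = (
    "od_raw",
    "od_enhanced",
    "local_mean",
    "local_sd",
    "ridge",
    "anisotropy",
)


class ParameterError(ValueError):
    pass


@dataclass
class ODMap:
    """Per-channel and channel-averaged optical density."""

    values: np.ndarray  # (H, W) channel-averaged OD
    channels: np.ndarray | None  # (H, W, C) per-channel OD, None for grey input
    i0: np.ndarray  # reference white per channel
    od_max: float = DEFAULT_OD_MAX


def estimate_i0(image: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Reference white as a per-channel high percentile (background)."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[..., None]
    return np.maximum(np.percentile(img, percentile, axis=(0, 1)), 1.0)


def optical_density(image: np.ndarray, i0=None, od_max: float = DEFAULT_OD_MAX) -> ODMap:
    """OD_c = -log10(I_c / I0_c), clipped to [0, od_max]."""
    img = np.asarray(image, dtype=float)
    grey_input = img.ndim == 2
    if grey_input:
        img = img[..., None]
    if i0 is None:
        i0 = estimate_i0(img)
    i0 = np.atleast_1d(np.asarray(i0, dtype=float))
    if np.any(i0 <= 0):
        raise ParameterError("I0 must be positive per channel")
    if i0.size not in (1, img.shape[-1]):
        raise ParameterError("I0 must be scalar or per-channel")
    with np.errstate(divide="ignore"):
        od = -np.log10(img / i0)
    od = np.clip(od, 0.0, od_max)
    mean_od = od.mean(axis=-1)
    return ODMap(
        values=mean_od,
        channels=None if grey_input else od,
        i0=i0,
        od_max=od_max,
    )


def _median_background(od: np.ndarray, kernel_px: int, downscale: int = 8) -> np.ndarray:
    """Large-kernel median background, computed on a decimated grid for speed."""
    if downscale > 1 and min(od.shape) > 4 * downscale:
        small = resize(od, (od.shape[0] // downscale, od.shape[1] // downscale),
                       order=1, anti_aliasing=True, preserve_range=True)
        med = ndi.median_filter(small, size=max(3, kernel_px // downscale))
        return resize(med, od.shape, order=1, preserve_range=True)
    return ndi.median_filter(od, size=kernel_px)


def _ridge_response(od: np.ndarray, sigmas_px) -> np.ndarray:
    """Largest negative second directional derivative across scales.

    Bright (high-OD) ridges give a large negative Hessian eigenvalue; the
    response is scale-normalized and clipped at zero.
    """
    best = np.zeros_like(od, dtype=float)
    for s in sigmas_px:
        h = hessian_matrix(od, sigma=s, order="rc", use_gaussian_derivatives=False)
        ev = hessian_matrix_eigvals(h)  # ev[1] is the smaller eigenvalue
        resp = np.maximum(-ev[1] * s**2, 0.0)
        best = np.maximum(best, resp)
    return best


def enhance_fibers(
    od: ODMap,
    n_iter: int = 2,
    scales_um=DEFAULT_SCALES_UM,
    resolution: float = 0.46,
    background_kernel_um: float = 50.0,
) -> ODMap:
    """Iterative enhancement: subtract median background, add ridge response,
    renormalize to the input OD range."""
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    scales_um = tuple(scales_um)
    if not scales_um:
        raise ParameterError("scales_um must be non-empty")
    sigmas_px = [max(0.8, s / resolution) for s in scales_um]
    kernel_px = max(5, int(round(background_kernel_um / resolution)) | 1)
    values = od.values.astype(float)
    in_min, in_max = float(values.min()), float(values.max())
    out = values.copy()
    for _ in range(n_iter):
        out = np.maximum(out - _median_background(out, kernel_px), 0.0)
        ridge = _ridge_response(out, sigmas_px)
        peak = float(ridge.max())
        # multiplicative gain keeps a near-zero background near zero; the
        # mild power squash suppresses residual background further each
        # pass, so fiber/background contrast grows with iterations
        if peak > 0:
            out = out * (1.0 + ridge / peak) + ridge
        hi = float(out.max())
        if hi > 0:
            out = (out / hi) ** 1.25 * (in_max - in_min) + in_min
        else:
            out = np.zeros_like(out)
    return ODMap(values=out, channels=None, i0=od.i0, od_max=od.od_max)


def pixel_features(
    od: ODMap,
    od_enhanced: ODMap,
    window_px: int = DEFAULT_FEATURE_WINDOW,
    resolution: float = 0.46,
) -> np.ndarray:
    """(H, W, 6) float32 feature stack; see FEATURE_NAMES for the order."""
    if window_px < 3 or window_px % 2 == 0:
        raise ParameterError("window_px must be odd and >= 3")
    if window_px > min(od.values.shape):
        raise ParameterError("window larger than image")
    raw = od.values.astype(np.float32)
    enh = od_enhanced.values.astype(np.float32)
    local_mean = ndi.uniform_filter(enh, size=window_px)
    local_sq = ndi.uniform_filter(enh * enh, size=window_px)
    local_sd = np.sqrt(np.maximum(local_sq - local_mean**2, 0.0))
    sigma = max(1.0, 2.0 / resolution / 2.0)
    ridge = _ridge_response(enh.astype(float), [sigma]).astype(np.float32)
    axx, axy, ayy = structure_tensor(enh, sigma=sigma, order="rc")
    # eigenvalue-ratio anisotropy (coherence) of the window structure tensor
    tr = axx + ayy
    det = axx * ayy - axy * axy
    disc = np.sqrt(np.maximum((tr / 2) ** 2 - det, 0.0))
    l1, l2 = tr / 2 + disc, tr / 2 - disc
    anisotropy = np.where(l1 + l2 > 1e-12, (l1 - l2) / (l1 + l2 + 1e-12), 0.0)
    stack = np.stack(
        [raw, enh, local_mean, local_sd, ridge, anisotropy.astype(np.float32)], axis=-1
    )
    return stack.astype(np.float32)


@dataclass
class LogitModel:
    """Logistic pixel classifier; predictions are a pure function of the
    stored weights, so JSON round-trips preserve them exactly."""

    feature_names: tuple[str, ...]
    weights: np.ndarray  # per feature
    intercept: float
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    n_pixels: int = 0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "scale_mean": self.scale_mean.tolist(),
                "scale_sd": self.scale_sd.tolist(),
                "n_pixels": self.n_pixels,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LogitModel":
        d = json.loads(text)
        return cls(
            feature_names=tuple(d["feature_names"]),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            scale_mean=np.asarray(d["scale_mean"], dtype=float),
            scale_sd=np.asarray(d["scale_sd"], dtype=float),
            n_pixels=int(d["n_pixels"]),
            seed=int(d["seed"]),
        )


class DegenerateTrainingError(ValueError):
    pass


def fit_pixel_logit(
    features: np.ndarray,
    labels: np.ndarray,
    n_sample: int = 100_000,
    seed: int = 0,
    feature_names=FEATURE_NAMES,
) -> LogitModel:
    """Maximum-likelihood logistic fit on a class-balanced pixel sample."""
    x = np.asarray(features, dtype=np.float64).reshape(-1, features.shape[-1])
    y = np.asarray(labels).reshape(-1).astype(bool)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateTrainingError("both classes must be present")
    rng = np.random.default_rng(seed)
    per_class = max(1, n_sample // 2)
    pos_take = rng.choice(pos, size=min(per_class, len(pos)), replace=False)
    neg_take = rng.choice(neg, size=min(per_class, len(neg)), replace=False)
    take = np.concatenate([pos_take, neg_take])
    xs, ys = x[take], y[take]
    mean = xs.mean(axis=0)
    sd = xs.std(axis=0)
    sd[sd == 0] = 1.0
    xs_std = (xs - mean) / sd
    clf = LogisticRegression(C=1e4, max_iter=2000, tol=1e-8)
    clf.fit(xs_std, ys)
    return LogitModel(
        feature_names=tuple(feature_names),
        weights=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        scale_mean=mean,
        scale_sd=sd,
        n_pixels=len(take),
        seed=seed,
    )


def probability_map(
    model: LogitModel, features: np.ndarray, feature_names=FEATURE_NAMES
) -> np.ndarray:
    """p = logistic(intercept + w . x) per pixel, in the model's feature order."""
    feature_names = tuple(feature_names)
    if set(feature_names) != set(model.feature_names):
        raise KeyError("feature names do not match the model")
    order = [feature_names.index(n) for n in model.feature_names]
    x = np.asarray(features, dtype=np.float64)[..., order]
    x = (x - model.scale_mean) / model.scale_sd
    z = model.intercept + x @ model.weights
    from scipy.special import expit

    return expit(z)


@dataclass
class FiberSet:
    """Contiguously labeled connected components."""

    labels: np.ndarray  # (H, W) int, 0 = background
    resolution: float
    n_fibers: int = field(init=False)

    def __post_init__(self):
        self.n_fibers = int(self.labels.max())


def segment_fibers(
    prob: np.ndarray,
    threshold: float = 0.5,
    min_area_um2: float = 10.0,
    resolution: float = 0.46,
) -> FiberSet:
    """Threshold the probability map and keep 8-connected components with
    area >= min_area_um2."""
    if not 0.0 < threshold < 1.0:
        raise ParameterError("threshold must lie in (0, 1)")
    mask = np.asarray(prob) >= threshold
    labels = cc_label(mask, connectivity=2)
    min_px = min_area_um2 / resolution**2
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_px)
    keep = keep[keep != 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return FiberSet(labels=remap[labels], resolution=resolution)


def roc_auc(prob: np.ndarray, truth_mask: np.ndarray) -> float:
    """Pixel-wise AUC: probability that a random fiber pixel outscores a
    random background pixel, ties counting one half."""
    return rank_auc(np.asarray(prob).ravel(), np.asarray(truth_mask).ravel())
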