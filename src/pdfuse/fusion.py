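"""Image preprocessing: exposure-fusion enhancement, mean filtering, and
morphological-gradient-driven fusion.

Two copies of each input slice are prepared — a contrast-enhanced copy built
with a camera-response brightness transform and a per-pixel illumination
weight, and a denoised copy from a box mean filter — and then blended into a
single fused image.  The blend is driven by the multi-scale morphological
gradient (MSMG), a classical focus/contrast measure: at each pixel the copy
with the stronger local gradient dominates.

Formulas
--------
Brightness transform (camera response, beta-gamma form)::

    g(P, k) = exp(b * (1 - k**a)) * P ** (k**a)

with constants ``a = 0.3293``, ``b = 1.158`` by default (configurable; the
camera-response literature this family descends from uses a negative ``a`` —
see the methods note for the consequences of the sign).

Enhanced image::

    R = W * P + (1 - W) * g(P, k)

where ``W`` is a per-pixel well-exposedness weight in [0, 1] and ``k`` the
exposure ratio maximizing the intensity entropy of the underexposed pixels.

MSMG::

    G_t = dilation(f, SE_t) - erosion(f, SE_t),   SE_t = t-fold scaled disk
    M   = sum_t w_t * G_t,                        w_t = 1 / (2t + 1)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import (
    binary_dilation,
    gaussian_filter,
    grey_dilation,
    grey_erosion,
    uniform_filter,
)
from skimage.morphology import disk

__all__ = [
    "FusionConfig",
    "EnhancementResult",
    "GradientMap",
    "btf",
    "illumination_weight",
    "find_exposure_ratio",
    "enhance",
    "mean_filter",
    "msmg",
    "msmg_weights",
    "fuse",
    "preprocess_image",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class FusionConfig:
    btf_a: float = 0.3293
    btf_b: float = 1.158
    k_search_range: tuple[float, float] = (1.0, 8.0)
    underexposed_threshold: float = 0.5
    weight_smoothing_sigma: float = 5.0
    weight_exponent: float = 0.5
    mean_filter_window: int = 3
    msmg_scales: int = 3
    base_se_radius: int = 1
    blend_mode: str = "soft"
    soft_sharpness: float = 4.0
    entropy_bins: int = 256
    entropy_max_pixels: int = 2048
    border_mode: str = "reflect"
    fuse_with: str = "filtered"  # alternative: "original"

    def __post_init__(self) -> None:
        if self.mean_filter_window < 3 or self.mean_filter_window % 2 == 0:
            raise ValueError("mean_filter_window must be odd and >= 3")
        if self.msmg_scales < 1:
            raise ValueError("msmg_scales must be >= 1")
        lo, hi = self.k_search_range
        if not (0 < lo <= hi):
            raise ValueError("k_search_range must lie within (0, inf)")
        if self.blend_mode not in ("soft", "hard"):
            raise ValueError(f"unknown blend_mode {self.blend_mode!r}")


@dataclass
class EnhancementResult:
    enhanced: np.ndarray
    weight_map: np.ndarray
    exposure_ratio: float
    synthetic_exposure: np.ndarray


@dataclass
class GradientMap:
    values: np.ndarray
    scales_used: int
    per_scale: np.ndarray | None = None


def _check_image(image: np.ndarray, name: str = "image") -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {image.shape}")
    if np.isnan(image).any():
        raise ValueError(f"{name} contains NaN pixels")
    return image


def btf(image: np.ndarray, k: float, config: FusionConfig | None = None) -> np.ndarray:
    """Brightness transform g(P, k) = e^{b(1-k^a)} * P^{k^a}, clipped to [0,1]."""
    config = config or FusionConfig()
    image = np.asarray(image, dtype=np.float64)
    if np.isnan(image).any():
        raise ValueError("image contains NaN pixels")
    if not np.isfinite(k) or k <= 0:
        raise ValueError(f"exposure ratio k must be > 0, got {k}")
    gamma = k**config.btf_a
    beta = np.exp(config.btf_b * (1.0 - gamma))
    return np.clip(beta * np.power(image, gamma), 0.0, 1.0)


def illumination_weight(image: np.ndarray, config: FusionConfig | None = None) -> np.ndarray:
    """Well-exposedness weight W = (smoothed luminance) ** mu, in [0,1]."""
    config = config or FusionConfig()
    image = _check_image(image)
    smooth = gaussian_filter(image, sigma=config.weight_smoothing_sigma,
                             mode=config.border_mode)
    return np.clip(smooth, 0.0, 1.0) ** config.weight_exponent


def _entropy(values: np.ndarray, bins: int) -> float:
    hist, _ = np.histogram(values, bins=bins, range=(0.0, 1.0))
    p = hist[hist > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def find_exposure_ratio(
    image: np.ndarray,
    W: np.ndarray,
    config: FusionConfig | None = None,
) -> float:
    """Exposure ratio maximizing the entropy of the brightened underexposed set.

    Coarse grid scan (step 0.01) followed by golden-section refinement around
    the best grid point; flat landscapes (and ties) resolve to the smallest k.
    If no pixel is underexposed the defined fallback is k = 1.
    """
    config = config or FusionConfig()
    image = _check_image(image)
    if image.size == 0:
        raise ValueError("empty image")
    Q = image[np.asarray(W) < config.underexposed_threshold]
    if Q.size == 0:
        return 1.0
    if Q.size > config.entropy_max_pixels:
        # Deterministic even subsample; the entropy of the brightened set is
        # insensitive to this thinning at these sizes.
        step = int(np.ceil(Q.size / config.entropy_max_pixels))
        Q = Q[::step]
    lo, hi = config.k_search_range

    def h(k: float) -> float:
        return _entropy(btf(Q, k, config), config.entropy_bins)

    ks = np.arange(lo, hi + 1e-12, 0.01)
    ent = np.array([h(k) for k in ks])
    if ent.max() - ent.min() < 1e-12:
        return float(lo)
    best = int(np.flatnonzero(ent >= ent.max() - 1e-12)[0])  # smallest tied k
    a = ks[max(best - 1, 0)]
    b = ks[min(best + 1, len(ks) - 1)]
    # Golden-section refinement inside the bracketing interval.
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1, f2 = h(x1), h(x2)
    while b - a > 1e-3:
        if f1 >= f2:  # prefer the left side on ties
            b, x2, f2 = x2, x1, f1
            x1 = b - _GOLDEN * (b - a)
            f1 = h(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + _GOLDEN * (b - a)
            f2 = h(x2)
    k_ref = float(a if h(a) >= h(b) else b)
    return k_ref if h(k_ref) > ent[best] + 1e-12 else float(ks[best])


def enhance(image: np.ndarray, config: FusionConfig | None = None) -> EnhancementResult:
    """Exposure-fusion enhancement R = W*P + (1-W)*g(P, k)."""
    config = config or FusionConfig()
    image = _check_image(image)
    W = illumination_weight(image, config)
    k = find_exposure_ratio(image, W, config)
    g = btf(image, k, config)
    R = np.clip(W * image + (1.0 - W) * g, 0.0, 1.0)
    return EnhancementResult(enhanced=R, weight_map=W, exposure_ratio=k,
                             synthetic_exposure=g)


def mean_filter(image: np.ndarray, window: int = 3, mode: str = "reflect") -> np.ndarray:
    """Box mean over an odd square window, reflect-padded borders."""
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    image = _check_image(image)
    return uniform_filter(image, size=window, mode=mode)


def msmg_weights(n_scales: int) -> np.ndarray:
    """Scale weights w_t = 1/(2t+1), t = 1..N."""
    return np.array([1.0 / (2 * t + 1) for t in range(1, n_scales + 1)])


def msmg(image: np.ndarray, config: FusionConfig | None = None,
         keep_per_scale: bool = False) -> GradientMap:
    """Multi-scale morphological gradient M = sum_t w_t (f⊕SE_t − f⊖SE_t).

    SE_t is the (t−1)-fold dilation of the flat base structuring element, i.e.
    a disk of radius t for the default radius-1 disk base.  Only flat
    (boolean) structuring elements are supported.
    """
    config = config or FusionConfig()
    image = _check_image(image)
    base = disk(config.base_se_radius).astype(bool)
    if base.dtype != bool:  # pragma: no cover - disk is always boolean here
        raise ValueError("only flat (boolean) structuring elements are supported")
    weights = msmg_weights(config.msmg_scales)
    se = base
    M = np.zeros_like(image)
    stack = [] if keep_per_scale else None
    for t in range(1, config.msmg_scales + 1):
        g_t = (grey_dilation(image, footprint=se, mode=config.border_mode)
               - grey_erosion(image, footprint=se, mode=config.border_mode))
        M += weights[t - 1] * g_t
        if keep_per_scale:
            stack.append(g_t)
        se = binary_dilation(se, structure=base)
    per_scale = np.stack(stack) if keep_per_scale else None
    return GradientMap(values=M, scales_used=config.msmg_scales, per_scale=per_scale)


def fuse(enhanced: np.ndarray, filtered: np.ndarray,
         config: FusionConfig | None = None) -> np.ndarray:
    """Blend the two preprocessed copies using MSMG as the focus measure.

    soft mode: rho = logistic(soft_sharpness * (M_enh − M_filt)), output
    rho*enhanced + (1−rho)*filtered.  hard mode: per-pixel winner by MSMG,
    ties going to the enhanced copy.
    """
    config = config or FusionConfig()
    enhanced = _check_image(enhanced, "enhanced")
    filtered = _check_image(filtered, "filtered")
    if enhanced.shape != filtered.shape:
        raise ValueError(
            f"shape mismatch: {enhanced.shape} vs {filtered.shape}")
    m_e = msmg(enhanced, config).values
    m_f = msmg(filtered, config).values
    if config.blend_mode == "hard":
        out = np.where(m_e >= m_f, enhanced, filtered)
    else:
        rho = 1.0 / (1.0 + np.exp(-config.soft_sharpness * (m_e - m_f)))
        out = rho * enhanced + (1.0 - rho) * filtered
    return np.clip(out, 0.0, 1.0)


def preprocess_image(image: np.ndarray, config: FusionConfig | None = None):
    """Full preprocessing of one slice.

    Returns (fused, stats) where stats carries the per-image quantities of
    interest: exposure ratio k, mean illumination weight, mean MSMG of the
    fused output.
    """
    config = config or FusionConfig()
    res = enhance(image, config)
    filtered = mean_filter(image, config.mean_filter_window, config.border_mode)
    other = filtered if config.fuse_with == "filtered" else image
    fused = fuse(res.enhanced, other, config)
    stats = {
        "k": res.exposure_ratio,
        "mean_W": float(res.weight_map.mean()),
        "mean_M": float(msmg(fused, config).values.mean()),
    }
    return fused, stats
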