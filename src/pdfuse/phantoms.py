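"""Synthetic brain-slice phantoms with class-dependent morphology.

Real Parkinson's imaging cohorts (e.g. T1-weighted MRI collections) are
access-controlled, so the package ships a generator of grayscale brain-like
slices whose *geometry* carries the severity label: the dark interior
"ventricle" region grows and the bright cortical band thins from mild to
moderate to severe.  Intensity statistics (texture, shading, noise) are
class-independent by design, so a classifier has to pick up shape, not a
mean-brightness shortcut.

Images are float arrays in [0, 1].  Written to disk they are 8-bit PNGs
(lossless; read back as value/255).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec",
    "CLASS_NAMES",
    "generate_phantom",
    "ventricle_area",
    "generate_dataset",
    "load_image",
    "save_image",
    "export_nifti",
]

CLASS_NAMES = ("mild", "moderate", "severe")

# Geometry defaults per class index: ventricle size multiplier and cortical
# band thickness multiplier.  Ventricle area scales ~ quadratically with the
# first factor, which keeps the three classes separable by area alone while
# per-image jitter (sigma below) leaves some overlap in rendered images.
_VENTRICLE_SCALE = (0.7, 1.0, 1.3)
_CORTEX_THICKNESS = (1.15, 1.0, 0.85)

# Flat intensity levels for the noiseless piecewise-constant phantom.
_LEVEL_BACKGROUND = 0.0
_LEVEL_TISSUE = 0.55
_LEVEL_CORTEX = 0.85
_LEVEL_VENTRICLE = 0.12


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    ventricle_scale defaults to the class-dependent value; pass explicitly to
    override.  All sigmas are in intensity units on the [0, 1] scale.
    """

    image_size: int = 128
    class_label: int = 0
    ventricle_scale: float | None = None
    texture_sigma: float = 0.04
    noise_sigma: float = 0.03
    illumination_gradient: float = 0.2
    jitter_sigma: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in (0, 1, 2):
            raise ValueError(
                f"class_label must be 0 (mild), 1 (moderate) or 2 (severe), "
                f"got {self.class_label!r}"
            )
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if not 0.0 <= self.illumination_gradient <= 0.6:
            raise ValueError("illumination_gradient must lie in [0, 0.6]")

    @property
    def effective_ventricle_scale(self) -> float:
        if self.ventricle_scale is not None:
            return self.ventricle_scale
        return _VENTRICLE_SCALE[self.class_label]


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _masks(spec: PhantomSpec, rng: np.random.Generator):
    """Build the brain / cortex / ventricle masks (pure geometry)."""
    s = spec.image_size
    cy = cx = (s - 1) / 2.0
    jit = lambda: float(np.exp(rng.normal(0.0, spec.jitter_sigma)))  # noqa: E731

    brain_ry = 0.42 * s * jit() ** 0.5
    brain_rx = 0.34 * s * jit() ** 0.5
    brain = _ellipse_mask(s, cy, cx, brain_ry, brain_rx)

    # Cortical band: between the brain boundary and an inner ellipse.
    thick = 0.10 * _CORTEX_THICKNESS[spec.class_label] * jit()
    inner = _ellipse_mask(s, cy, cx, brain_ry * (1 - thick), brain_rx * (1 - thick))
    cortex = brain & ~inner

    # Two mirrored para-central ventricle lobes.
    vscale = spec.effective_ventricle_scale * jit()
    v_ry = 0.16 * s * vscale
    v_rx = 0.055 * s * vscale
    off = 0.07 * s
    left = _ellipse_mask(s, cy, cx - off, v_ry, v_rx)
    right = _ellipse_mask(s, cy, cx + off, v_ry, v_rx)
    ventricle = (left | right) & inner
    return brain, cortex, ventricle


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one phantom slice; deterministic for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    brain, cortex, ventricle = _masks(spec, rng)
    s = spec.image_size

    img = np.full((s, s), _LEVEL_BACKGROUND, dtype=np.float64)
    img[brain] = _LEVEL_TISSUE
    img[cortex] = _LEVEL_CORTEX
    img[ventricle] = _LEVEL_VENTRICLE

    if spec.texture_sigma > 0:
        texture = gaussian_filter(rng.standard_normal((s, s)), sigma=2.0)
        texture /= max(texture.std(), 1e-12)
        img = np.where(brain, img + spec.texture_sigma * texture, img)

    if spec.illumination_gradient > 0:
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:s, 0:s]
        ramp = (np.cos(theta) * (xx / (s - 1) - 0.5)
                + np.sin(theta) * (yy / (s - 1) - 0.5))
        img = img * (1.0 + spec.illumination_gradient * ramp)

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=(s, s))

    return np.clip(img, 0.0, 1.0)


def ventricle_area(spec: PhantomSpec) -> int:
    """Pixel count of the ventricle mask before rendering (the label signal)."""
    rng = np.random.default_rng(spec.seed)
    _, _, ventricle = _masks(spec, rng)
    return int(ventricle.sum())


def save_image(img: np.ndarray, path: str) -> None:
    """Write a [0,1] float image as 8-bit grayscale PNG (lossless)."""
    arr = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_image(path: str) -> np.ndarray:
    """Read an image file back to float64 in [0,1]."""
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
    return arr / 255.0


def _child_seed(seed: int, index: int) -> int:
    # Stable derived seed, kept below 2**31.
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31 - 1))


def generate_dataset(
    n_per_class: int,
    out_dir: str,
    spec_defaults: PhantomSpec | None = None,
    split_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a stratified labeled phantom dataset on disk.

    Each class contributes ``round(split_fraction * n_per_class)`` training
    images and the remainder to the test split.  Writes the PNGs plus a
    ``manifest.csv`` with columns (path, label, split, seed) and returns the
    (train, test) manifest frames.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2 to populate both splits")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie strictly between 0 and 1")
    n_train = int(round(split_fraction * n_per_class))
    if n_train == 0 or n_train == n_per_class:
        raise ValueError(
            f"split_fraction={split_fraction} leaves an empty split for "
            f"n_per_class={n_per_class}"
        )
    base = spec_defaults or PhantomSpec()
    os.makedirs(out_dir, exist_ok=True)

    rows = []
    index = 0
    for label in range(3):
        for i in range(n_per_class):
            child = _child_seed(seed, index)
            spec = replace(base, class_label=label, ventricle_scale=None, seed=child)
            img = generate_phantom(spec)
            name = f"{CLASS_NAMES[label]}_{i:04d}.png"
            path = os.path.join(out_dir, name)
            save_image(img, path)
            split = "train" if i < n_train else "test"
            rows.append({"path": path, "label": label, "split": split, "seed": child})
            index += 1

    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    train = manifest[manifest.split == "train"].reset_index(drop=True)
    test = manifest[manifest.split == "test"].reset_index(drop=True)
    return train, test


def export_nifti(images: list[np.ndarray], path: str) -> None:
    """Stack 2-D slices into a 3-D NIfTI volume (optional convenience)."""
    import nibabel as nib

    vol = np.stack(images, axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), path)
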