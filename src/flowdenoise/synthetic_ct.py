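"""Synthetic CT-like phantoms, patches and noisy counterparts.

Piecewise-constant ellipse anatomy in Hounsfield units on a square grid,
plus a stationary correlated-Gaussian degradation operator standing in for
the catch-all noise of a real scanner.  Everything is a pure function of
its arguments including the seed, so training, sampling and evaluation run
with no external data.

Geometry convention: ellipse centers and semi-axes are fractions of the
field of view, with FOV coordinates [-1, 1]^2 mapped to the pixel grid and
pixel centers at half-integers.  Later ellipses overwrite earlier ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "DegradationConfig",
    "PatchSet",
    "generate_phantom",
    "degrade",
    "extract_patches",
    "make_paired_eval_set",
    "default_head_spec",
]


@dataclass(frozen=True)
class Ellipse:
    center: Tuple[float, float]  # FOV fractions in [-1, 1]
    semi_axes: Tuple[float, float]  # FOV fractions, > 0
    rotation_deg: float
    hu: float

    def __post_init__(self) -> None:
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValueError(f"semi-axes must be > 0, got {self.semi_axes}")
        if not (-1 <= self.center[0] <= 1 and -1 <= self.center[1] <= 1):
            raise ValueError(f"center must lie in [-1, 1]^2, got {self.center}")


@dataclass(frozen=True)
class PhantomSpec:
    ellipses: Tuple[Ellipse, ...]
    background_hu: float = -1000.0
    image_size: int = 64

    def __post_init__(self) -> None:
        if self.image_size < 8:
            raise ValueError(f"image_size must be >= 8, got {self.image_size}")


@dataclass(frozen=True)
class DegradationConfig:
    """Correlated zero-mean Gaussian noise: white noise smoothed by an
    isotropic Gaussian of SD ``correlation_length`` pixels, renormalized so
    the marginal SD equals ``noise_sd``."""

    noise_sd: float = 50.0
    correlation_length: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be >= 0")


@dataclass
class PatchSet:
    patches: List[np.ndarray]
    patch_size: int
    source_ids: List[int]
    seed: int


def _fov_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates in [-1, 1]; exact half-integer convention."""
    coords = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    return np.meshgrid(coords, coords, indexing="xy")


def generate_phantom(
    spec: PhantomSpec,
    rng_seed: int = 0,
    center_jitter: float = 0.0,
    hu_jitter: float = 0.0,
) -> np.ndarray:
    """Render a phantom; optional seed-driven jitter of centers and HU values.

    Jittered centers falling outside the FOV are clipped with a warning.
    """
    rng = np.random.default_rng(rng_seed)
    n = spec.image_size
    X, Y = _fov_grid(n)
    img = np.full((n, n), float(spec.background_hu))
    for e in spec.ellipses:
        cx, cy = e.center
        hu = e.hu
        if center_jitter > 0:
            cx += rng.normal(0, center_jitter)
            cy += rng.normal(0, center_jitter)
            if abs(cx) > 1 or abs(cy) > 1:
                warnings.warn(
                    f"jittered ellipse center ({cx:.3f}, {cy:.3f}) outside FOV; clipping",
                    stacklevel=2,
                )
                cx, cy = float(np.clip(cx, -1, 1)), float(np.clip(cy, -1, 1))
        if hu_jitter > 0:
            hu += rng.normal(0, hu_jitter)
        theta = np.deg2rad(e.rotation_deg)
        dx, dy = X - cx, Y - cy
        xr = dx * np.cos(theta) + dy * np.sin(theta)
        yr = -dx * np.sin(theta) + dy * np.cos(theta)
        inside = (xr / e.semi_axes[0]) ** 2 + (yr / e.semi_axes[1]) ** 2 <= 1.0
        img[inside] = hu
    return img


def _correlated_noise(
    shape: tuple, config: DegradationConfig, rng: np.random.Generator
) -> np.ndarray:
    white = rng.standard_normal(shape)
    if config.correlation_length == 0:
        return config.noise_sd * white
    smooth = ndimage.gaussian_filter(white, config.correlation_length, mode="wrap")
    # variance renormalization via the effective kernel's L2 norm
    impulse = np.zeros(shape)
    impulse[shape[0] // 2, shape[1] // 2] = 1.0
    kernel = ndimage.gaussian_filter(impulse, config.correlation_length, mode="wrap")
    return config.noise_sd * smooth / np.sqrt(np.sum(kernel**2))


def degrade(image: np.ndarray, config: DegradationConfig) -> np.ndarray:
    """Apply the stochastic degradation operator; deterministic given the seed."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if config.noise_sd == 0:
        return np.array(image)
    rng = np.random.default_rng(config.seed)
    return image + _correlated_noise(image.shape, config, rng)


def extract_patches(
    images: Sequence[np.ndarray], patch_size: int, count: int, seed: int = 0
) -> PatchSet:
    """``count`` square patches drawn uniformly over valid top-left corners."""
    for idx, img in enumerate(images):
        if img.shape[0] < patch_size or img.shape[1] < patch_size:
            raise ValueError(
                f"patch_size {patch_size} exceeds image {idx} of shape {img.shape}"
            )
    rng = np.random.default_rng(seed)
    patches, sources = [], []
    for _ in range(count):
        k = int(rng.integers(len(images)))
        img = images[k]
        i = int(rng.integers(img.shape[0] - patch_size + 1))
        j = int(rng.integers(img.shape[1] - patch_size + 1))
        patches.append(np.array(img[i : i + patch_size, j : j + patch_size]))
        sources.append(k)
    return PatchSet(patches=patches, patch_size=patch_size, source_ids=sources, seed=seed)


def make_paired_eval_set(
    n_images: int,
    spec_template: PhantomSpec,
    degradation: DegradationConfig,
    seed: int = 0,
    center_jitter: float = 0.03,
    hu_jitter: float = 20.0,
) -> tuple[List[np.ndarray], List[np.ndarray]]:
    """Element-wise paired (clean, noisy) evaluation sets.

    Clean images vary across ``i`` through seed-driven jitter of the
    template; ``noisy[i]`` differs from ``clean[i]`` only by the
    degradation.  Evaluation-only: the training pathway never sees pairs.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    ss = np.random.SeedSequence([seed, 0x9A1])
    child_seeds = ss.generate_state(2 * n_images)
    clean, noisy = [], []
    for i in range(n_images):
        y = generate_phantom(
            spec_template,
            rng_seed=int(child_seeds[2 * i]),
            center_jitter=center_jitter,
            hu_jitter=hu_jitter,
        )
        cfg_i = replace(degradation, seed=int(child_seeds[2 * i + 1]))
        clean.append(y)
        noisy.append(degrade(y, cfg_i))
    return clean, noisy


def default_head_spec(image_size: int = 64) -> PhantomSpec:
    """A simple head-like phantom: skull ring, brain, ventricles, a lesion."""
    return PhantomSpec(
        ellipses=(
            Ellipse((0.0, 0.0), (0.80, 0.92), 0.0, 800.0),   # skull
            Ellipse((0.0, 0.0), (0.70, 0.82), 0.0, 40.0),    # brain
            Ellipse((-0.18, 0.05), (0.12, 0.28), -15.0, 5.0),  # ventricle L
            Ellipse((0.18, 0.05), (0.12, 0.28), 15.0, 5.0),    # ventricle R
            Ellipse((0.25, -0.35), (0.10, 0.08), 0.0, 80.0),   # lesion
        ),
        background_hu=-1000.0,
        image_size=image_size,
    )
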