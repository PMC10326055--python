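"""Stimulus generation and preprocessing.

Images start as raw grayscale grids with pixel values in [0, 1]. A trial's
stimulus is produced by scaling by a contrast factor mu, normalizing to
[-1, 1], adding i.i.d. Gaussian pixel noise, and clamping back to [-1, 1]
(a hard-tanh threshold). The noise parameter sigma follows the convention
used throughout this package: by default it is the standard deviation of
the pixel noise on the [-1, 1] scale; a variance interpretation is
available via ``sigma_is_variance=True``.

Tasks with two superimposed stimuli combine the two contrast-scaled images
by an element-wise maximum before noise is added.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

IMG_SIZE = 32

STANDARD_CONTRAST_RANGE = (0.1, 1.0)
STANDARD_NOISE_RANGE = (1.0, 2.0)  # two-class / ten-class image tasks
GABOR_NOISE_RANGE = (0.5, 1.0)  # orientation-discrimination RL task
FIXED_MU_VALUE = 0.5
FIXED_SIGMA_VALUE = 1.5
MU_OVER_SIGMA_RATIO = 3.75  # sigma = 3.75 * mu in the fixed-ratio regime


@dataclass
class GaborSpec:
    """Oriented grating in a Gaussian window: tilt +/-5 deg from vertical,
    envelope sd 4 px, spatial frequency 0.3 cycles/px, 32x32 grid."""

    tilt: float = 5.0
    envelope_sd: float = 4.0
    spatial_frequency: float = 0.3
    size: int = IMG_SIZE

    def __post_init__(self):
        if self.tilt not in (-5.0, 5.0):
            raise ValueError(f"tilt must be -5 or +5 degrees, got {self.tilt}")
        if self.envelope_sd <= 0 or self.spatial_frequency <= 0 or self.size <= 0:
            raise ValueError("invalid GaborSpec")


@dataclass
class Regime:
    """A training/test regime: how per-trial (mu, sigma) pairs are sampled.

    ``standard``: mu ~ U[0.1, 1], sigma ~ U[1, 2].
    ``fixed_mu``: mu = 0.5, sigma ~ U[1, 2].
    ``fixed_sigma``: mu ~ U[0.1, 1], sigma = 1.5.
    ``fixed_mu_over_sigma``: mu ~ U[0.1, 1], sigma = 3.75 * mu.
    ``gabor``: mu ~ U[0.1, 1], sigma ~ U[0.5, 1] (RL orientation task).
    """

    name: str
    contrast_range: tuple = STANDARD_CONTRAST_RANGE
    noise_rule: object = STANDARD_NOISE_RANGE

    _KNOWN = ("standard", "fixed_mu", "fixed_sigma", "fixed_mu_over_sigma", "gabor")

    @classmethod
    def named(cls, name: str) -> "Regime":
        if name == "standard":
            return cls("standard", STANDARD_CONTRAST_RANGE, STANDARD_NOISE_RANGE)
        if name == "fixed_mu":
            return cls("fixed_mu", (FIXED_MU_VALUE, FIXED_MU_VALUE), STANDARD_NOISE_RANGE)
        if name == "fixed_sigma":
            return cls("fixed_sigma", STANDARD_CONTRAST_RANGE, (FIXED_SIGMA_VALUE, FIXED_SIGMA_VALUE))
        if name == "fixed_mu_over_sigma":
            return cls("fixed_mu_over_sigma", STANDARD_CONTRAST_RANGE, "ratio")
        if name == "gabor":
            return cls("gabor", STANDARD_CONTRAST_RANGE, GABOR_NOISE_RANGE)
        raise ValueError(f"unknown regime {name!r}; known: {cls._KNOWN}")


def sample_regime(regime: Regime | str, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw n per-trial (mu, sigma) pairs for a regime. Returns (n, 2)."""
    if isinstance(regime, str):
        regime = Regime.named(regime)
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = regime.contrast_range
    mu = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)
    if regime.noise_rule == "ratio":
        sigma = MU_OVER_SIGMA_RATIO * mu
    else:
        slo, shi = regime.noise_rule
        sigma = rng.uniform(slo, shi, size=n) if shi > slo else np.full(n, slo)
    return np.column_stack([mu, sigma])


def apply_contrast_noise(
    images: np.ndarray,
    mu: float | np.ndarray,
    sigma: float | np.ndarray,
    seed: int | np.random.Generator,
    sigma_is_variance: bool = False,
) -> np.ndarray:
    """Scale raw [0,1] images by contrast, normalize to [-1,1], add Gaussian
    pixel noise, and clamp to [-1,1].

    pixels_out = clamp(2 * mu * p - 1 + eps, -1, 1), eps ~ N(0, sd=sigma).
    Accepts a single image (H, W) or a batch (N, H, W); mu/sigma may be
    scalars or per-trial arrays of length N.
    """
    images = np.asarray(images, dtype=float)
    if not np.all(np.isfinite(images)):
        raise ValueError("non-finite pixels in raw images")
    if np.any(np.asarray(mu) < 0) or np.any(np.asarray(sigma) < 0):
        raise ValueError("mu and sigma must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    single = images.ndim == 2
    if single:
        images = images[None]
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (images.shape[0],))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (images.shape[0],))
    sd = np.sqrt(sigma) if sigma_is_variance else sigma
    scaled = 2.0 * mu[:, None, None] * images - 1.0
    noisy = scaled + rng.normal(size=images.shape) * sd[:, None, None]
    out = np.clip(noisy, -1.0, 1.0)
    return out[0] if single else out


def contrast_scale(images: np.ndarray, mu: float | np.ndarray) -> np.ndarray:
    """Contrast scaling and normalization only (no noise, no clamp needed
    before superimposition): 2 * mu * p - 1."""
    images = np.asarray(images, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if images.ndim == 3 and mu.ndim == 1:
        mu = mu[:, None, None]
    return 2.0 * mu * images - 1.0


def superimpose(x_s1: np.ndarray, x_s2: np.ndarray) -> np.ndarray:
    """Combine two contrast-scaled images by the element-wise maximum."""
    x_s1, x_s2 = np.asarray(x_s1, dtype=float), np.asarray(x_s2, dtype=float)
    if x_s1.shape != x_s2.shape:
        raise ValueError(f"shape mismatch: {x_s1.shape} vs {x_s2.shape}")
    return np.maximum(x_s1, x_s2)


def add_noise_clamp(scaled: np.ndarray, sigma, seed, sigma_is_variance: bool = False) -> np.ndarray:
    """Noise + clamp stage for already contrast-scaled ([-1,1]-normalized)
    images, e.g. after superimposition."""
    if np.any(np.asarray(sigma) < 0):
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    scaled = np.asarray(scaled, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (scaled.shape[0],)) if scaled.ndim == 3 else np.asarray(sigma, dtype=float)
    sd = np.sqrt(sigma) if sigma_is_variance else sigma
    if scaled.ndim == 3:
        sd = sd[:, None, None]
    return np.clip(scaled + rng.normal(size=scaled.shape) * sd, -1.0, 1.0)


def gabor_patch(spec: GaborSpec | None = None, tilt: float | None = None) -> np.ndarray:
    """Raw Gabor patch in [0, 1]: a cosine grating (phase zero at center)
    oriented ``tilt`` degrees from vertical, windowed by a centered Gaussian
    envelope, then rescaled from [-1, 1] to [0, 1]."""
    if spec is None:
        spec = GaborSpec(tilt=5.0 if tilt is None else tilt)
    n = spec.size
    half = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    xx -= half
    yy -= half
    theta = np.deg2rad(spec.tilt)
    # coordinate along the axis orthogonal to vertical stripes, rotated by tilt
    u = xx * np.cos(theta) + yy * np.sin(theta)
    grating = np.cos(2.0 * np.pi * spec.spatial_frequency * u)
    envelope = np.exp(-(xx**2 + yy**2) / (2.0 * spec.envelope_sd**2))
    return (grating * envelope + 1.0) / 2.0


@dataclass
class StimulusBatch:
    """Processed images plus per-trial metadata (label, mu, sigma)."""

    images: np.ndarray  # (N, 32, 32) in [-1, 1]
    meta: pd.DataFrame = field(default=None)  # columns: trial, label, mu, sigma

    def __post_init__(self):
        if self.meta is None:
            self.meta = pd.DataFrame({"trial": np.arange(len(self.images))})

    def __len__(self):
        return len(self.images)

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.save(path / "images.npy", self.images)
        self.meta.to_csv(path / "meta.csv", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "StimulusBatch":
        path = Path(path)
        return cls(np.load(path / "images.npy"), pd.read_csv(path / "meta.csv"))


def make_stimulus_batch(raw_images, labels, mu, sigma, seed, sigma_is_variance=False) -> StimulusBatch:
    """Process a batch of raw [0,1] images into stimuli with metadata."""
    images = apply_contrast_noise(raw_images, mu, sigma, seed, sigma_is_variance)
    n = len(images)
    meta = pd.DataFrame(
        {
            "trial": np.arange(n),
            "label": np.asarray(labels),
            "mu": np.broadcast_to(np.asarray(mu, dtype=float), (n,)),
            "sigma": np.broadcast_to(np.asarray(sigma, dtype=float), (n,)),
        }
    )
    return StimulusBatch(images, meta)


# ---------------------------------------------------------------------------
# Optional loader for the standard IDX image format (never required by tests)


def load_idx_images(path: str | Path, resize_to: int = IMG_SIZE) -> np.ndarray:
    """Load an IDX3 image file (as distributed for standard digit datasets)
    and bilinearly resize each image to ``resize_to`` x ``resize_to``,
    returning raw images scaled to [0, 1]."""
    with open(path, "rb") as fh:
        data = fh.read()
    magic, n, rows, cols = struct.unpack(">IIII", data[:16])
    if magic != 2051:
        raise ValueError(f"not an IDX3 image file (magic={magic})")
    imgs = np.frombuffer(data, dtype=np.uint8, offset=16).reshape(n, rows, cols).astype(float) / 255.0
    if rows == resize_to and cols == resize_to:
        return imgs
    return np.stack([_bilinear_resize(im, resize_to) for im in imgs])


def load_idx_labels(path: str | Path) -> np.ndarray:
    with open(path, "rb") as fh:
        data = fh.read()
    magic, n = struct.unpack(">II", data[:8])
    if magic != 2049:
        raise ValueError(f"not an IDX1 label file (magic={magic})")
    return np.frombuffer(data, dtype=np.uint8, offset=8).astype(int)


def _bilinear_resize(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape
    ys = (np.arange(size) + 0.5) * h / size - 0.5
    xs = (np.arange(size) + 0.5) * w / size - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    wy = np.clip(ys - y0, 0, 1)[:, None]
    wx = np.clip(xs - x0, 0, 1)[None, :]
    a = img[np.ix_(y0, x0)]
    b = img[np.ix_(y0, x1)]
    c = img[np.ix_(y1, x0)]
    d = img[np.ix_(y1, x1)]
    return a * (1 - wy) * (1 - wx) + b * (1 - wy) * wx + c * wy * (1 - wx) + d * wy * wx
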