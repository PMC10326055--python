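"""Download-free stand-in data.

Two generators make every pipeline stage testable offline:

* :func:`make_synthetic_classes` - a two-class 32x32 image family with
  handwriting-like within-class variability (smooth random affine warps and
  amplitude jitter around fixed class prototypes). A ``separation`` knob
  moves the class prototypes apart so discriminability is controllable.

* :func:`sample_latent_evidence` - labelled samples from two rotated,
  anisotropic 2-D Gaussians with class priors. This emulates the statistical
  structure of latent sensory-evidence distributions: elongated class
  distributions (major/minor sd ratio > 1) whose major axes are not
  parallel, the geometry under which optimal confidence deviates from a
  balance-of-evidence rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import IMG_SIZE

# Fitted latent statistics used as the package's reference geometry:
# major/minor sd ratio 2.44, angle between class major axes 51.4 degrees.
REFERENCE_AXIS_RATIO = 2.44
REFERENCE_AXIS_ANGLE_S1 = 30.0
REFERENCE_AXIS_ANGLE_S2 = 81.4


@dataclass
class LatentEvidenceSpec:
    """Two rotated anisotropic Gaussian classes in a 2-D evidence space."""

    mean_s1: tuple = (0.0, 0.0)
    mean_s2: tuple = (0.0, 0.0)
    sd_major: float = 1.0
    sd_minor: float = 1.0
    axis_angle_s1: float = 0.0  # degrees in [0, 180)
    axis_angle_s2: float = 0.0
    prior_s1: float = 0.5

    def __post_init__(self):
        if not (self.sd_major >= self.sd_minor > 0):
            raise ValueError("require sd_major >= sd_minor > 0")
        if not (0.0 <= self.prior_s1 <= 1.0):
            raise ValueError("prior_s1 must be a probability")

    def covariance(self, which: str) -> np.ndarray:
        angle = self.axis_angle_s1 if which == "s1" else self.axis_angle_s2
        th = np.deg2rad(angle)
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        d = np.diag([self.sd_major**2, self.sd_minor**2])
        return r @ d @ r.T

    def mean(self, which: str) -> np.ndarray:
        return np.asarray(self.mean_s1 if which == "s1" else self.mean_s2, dtype=float)


def reference_latent_spec(mean_radius: float = 1.5, sd_major: float = 0.9) -> LatentEvidenceSpec:
    """A spec matching the reference latent geometry: each class mean sits on
    its own major axis at ``mean_radius`` from the origin, axes 51.4 degrees
    apart, sd ratio 2.44."""
    a1, a2 = np.deg2rad(REFERENCE_AXIS_ANGLE_S1), np.deg2rad(REFERENCE_AXIS_ANGLE_S2)
    return LatentEvidenceSpec(
        mean_s1=(mean_radius * np.cos(a1), mean_radius * np.sin(a1)),
        mean_s2=(mean_radius * np.cos(a2), mean_radius * np.sin(a2)),
        sd_major=sd_major,
        sd_minor=sd_major / REFERENCE_AXIS_RATIO,
        axis_angle_s1=REFERENCE_AXIS_ANGLE_S1,
        axis_angle_s2=REFERENCE_AXIS_ANGLE_S2,
        prior_s1=0.5,
    )


def sample_latent_evidence(spec: LatentEvidenceSpec, n: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Sample n labelled 2-vectors from the spec. Returns (z, labels) with
    labels 0 for s1, 1 for s2."""
    if n <= 0:
        raise ValueError("n must be positive")
    for which in ("s1", "s2"):
        if np.linalg.eigvalsh(spec.covariance(which)).min() <= 0:
            raise ValueError("degenerate covariance")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = (rng.random(n) >= spec.prior_s1).astype(int)
    z = np.empty((n, 2))
    for lab, which in ((0, "s1"), (1, "s2")):
        idx = np.flatnonzero(labels == lab)
        if idx.size:
            z[idx] = rng.multivariate_normal(spec.mean(which), spec.covariance(which), size=idx.size)
    return z, labels


# ---------------------------------------------------------------------------
# Two-class image generator


def _prototypes(size: int = IMG_SIZE) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed deterministic prototypes: a shared centered blob plus two
    distinct oriented double-bar patterns (one per class)."""
    half = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    xx -= half
    yy -= half
    base = np.exp(-(xx**2 + yy**2) / (2 * 9.0**2))
    th1, th2 = np.deg2rad(45.0), np.deg2rad(-45.0)

    def bars(th):
        u = xx * np.cos(th) + yy * np.sin(th)
        v = -xx * np.sin(th) + yy * np.cos(th)
        stripe = np.exp(-((np.abs(u) - 5.0) ** 2) / (2 * 2.0**2))
        return stripe * np.exp(-(v**2) / (2 * 10.0**2))

    return base, bars(th1), bars(th2)


def _affine_warp(img: np.ndarray, rot_deg: float, shift: np.ndarray, scale: float) -> np.ndarray:
    """Inverse-mapped bilinear affine warp (rotate, scale, translate)."""
    size = img.shape[0]
    half = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    xx -= half
    yy -= half
    th = np.deg2rad(rot_deg)
    # inverse map: output coord -> input coord
    xs = (np.cos(th) * xx + np.sin(th) * yy) / scale + half - shift[0]
    ys = (-np.sin(th) * xx + np.cos(th) * yy) / scale + half - shift[1]
    x0 = np.clip(np.floor(xs).astype(int), 0, size - 1)
    y0 = np.clip(np.floor(ys).astype(int), 0, size - 1)
    x1 = np.clip(x0 + 1, 0, size - 1)
    y1 = np.clip(y0 + 1, 0, size - 1)
    wx = np.clip(xs - x0, 0, 1)
    wy = np.clip(ys - y0, 0, 1)
    out = (
        img[y0, x0] * (1 - wy) * (1 - wx)
        + img[y0, x1] * (1 - wy) * wx
        + img[y1, x0] * wy * (1 - wx)
        + img[y1, x1] * wy * wx
    )
    oob = (xs < 0) | (xs > size - 1) | (ys < 0) | (ys > size - 1)
    out[oob] = 0.0
    return out


def make_synthetic_classes(
    n_per_class: int,
    separation: float = 3.0,
    seed: int | np.random.Generator = 0,
    size: int = IMG_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate labelled raw [0,1] images for two synthetic classes.

    Each sample is a blend of a shared prototype and a class-specific
    oriented-bar prototype, warped by a small random affine transform
    (rotation up to +/-8 deg, sub-pixel-to-2px translation, 0.9-1.1 scale)
    with multiplicative amplitude jitter. ``separation=0`` makes the two
    class distributions identical; larger values increase the class weight
    in the blend. Returns (images, labels) with labels 0/1.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base, d1, d2 = _prototypes(size)
    lam = separation / (separation + 2.0)  # 0 -> identical classes, ->1 pure class pattern
    n = 2 * n_per_class
    labels = np.repeat([0, 1], n_per_class)
    images = np.empty((n, size, size))
    for i in range(n):
        delta = d1 if labels[i] == 0 else d2
        proto = (1.0 - lam) * base + lam * delta
        rot = rng.uniform(-8.0, 8.0)
        shift = rng.uniform(-2.0, 2.0, size=2)
        scale = rng.uniform(0.9, 1.1)
        amp = np.clip(rng.normal(1.0, 0.15), 0.4, 1.6)
        images[i] = np.clip(amp * _affine_warp(proto, rot, shift, scale), 0.0, 1.0)
    return images, labels
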