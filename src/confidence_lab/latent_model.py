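"""Denoising variational autoencoder and the latent-space ideal observer.

The VAE maps a noisy 32x32 stimulus to a 2-D latent posterior q(z|x)
(diagonal Gaussian, parameterized by mean and log-variance heads on the
shared convolutional encoder) and decodes a denoised reconstruction. The
loss is the per-image sum-of-squares reconstruction error against the
clean (pre-noise) target plus the KL divergence of q(z|x) from the unit
normal prior, both averaged over the batch.

The ideal observer fits one bivariate Gaussian per stimulus class to the
latent embeddings of labelled images and computes the exact class
posterior by Bayes' rule with equal priors. Decisions take the argmax
posterior; confidence is the maximum posterior, i.e. the probability of
being correct given z under the fitted class distributions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .stimuli import Regime, apply_contrast_noise, contrast_scale, sample_regime


class DegenerateGeometryWarning(UserWarning):
    pass


class VAE:
    """2-D latent denoising VAE (convolutional encoder, transposed-conv
    decoder with a tanh output so reconstructions live in [-1, 1])."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.enc_blocks = [
            nn.Sequential(nn.Conv2d(1, 32, 3, 2, 1, rng), nn.BatchNorm(32), nn.LeakyReLU(0.01)),
            nn.Sequential(nn.Conv2d(32, 32, 3, 2, 1, rng), nn.BatchNorm(32), nn.LeakyReLU(0.01)),
            nn.Sequential(nn.Conv2d(32, 32, 3, 2, 1, rng), nn.BatchNorm(32), nn.LeakyReLU(0.01)),
            nn.Sequential(nn.Flatten(), nn.Linear(512, 256, rng), nn.BatchNorm(256), nn.LeakyReLU(0.01)),
            nn.Sequential(nn.Linear(256, 128, rng), nn.BatchNorm(128), nn.LeakyReLU(0.01)),
        ]
        self.mean_head = nn.Linear(128, 2, rng)
        self.logvar_head = nn.Linear(128, 2, rng)
        self.decoder = nn.Sequential(
            nn.Linear(2, 128, rng),
            nn.LeakyReLU(0.01),
            nn.Linear(128, 256, rng),
            nn.LeakyReLU(0.01),
            nn.Reshape((16, 4, 4)),
            nn.ConvTranspose2d(16, 32, 4, 2, 1, rng),
            nn.LeakyReLU(0.01),
            nn.ConvTranspose2d(32, 32, 4, 2, 1, rng),
            nn.LeakyReLU(0.01),
            nn.ConvTranspose2d(32, 1, 4, 2, 1, rng),
            nn.Tanh(),
        )

    @property
    def latent_dim(self) -> int:
        return 2

    def params(self):
        enc = [p for b in self.enc_blocks for p in b.params()]
        return enc + self.mean_head.params() + self.logvar_head.params() + self.decoder.params()

    def encode(self, x, train=False):
        if x.ndim == 3:
            x = x[:, None]
        for b in self.enc_blocks:
            x = b.forward(x, train=train)
        return self.mean_head.forward(x, train=train), self.logvar_head.forward(x, train=train)

    def decode(self, z, train=False):
        return self.decoder.forward(z, train=train)[:, 0]

    def embed(self, x, use_posterior_means=True, rng=None) -> np.ndarray:
        """Posterior means (default) or posterior samples for a batch."""
        mean, logvar = self.encode(x, train=False)
        if use_posterior_means:
            return mean
        rng = np.random.default_rng(0) if rng is None else rng
        return mean + np.exp(0.5 * logvar) * rng.normal(size=mean.shape)


def kl_unit_normal(mean: np.ndarray, logvar: np.ndarray) -> float:
    """KL(q || N(0, I)) summed over latent dims, averaged over the batch."""
    return float(0.5 * np.mean(np.sum(mean**2 + np.exp(logvar) - logvar - 1.0, axis=1)))


def train_vae(
    vae: VAE,
    raw_images: np.ndarray,
    regime: Regime | str = "standard",
    epochs: int = 20,
    lr: float = 5e-4,
    batch_size: int = 32,
    seed: int = 0,
) -> pd.DataFrame:
    """Train the denoising VAE: noisy inputs are produced online by the
    contrast/noise pipeline; the reconstruction target is the clean image
    (contrast-scaled and clamped, before noise injection)."""
    if len(raw_images) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    opt = nn.Adam(vae.params(), lr=lr)
    n = len(raw_images)
    log = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        rec_losses, kls = [], []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if len(idx) < 2:
                continue
            musig = sample_regime(regime, len(idx), rng)
            clean = np.clip(contrast_scale(raw_images[idx], musig[:, 0]), -1.0, 1.0)
            noisy = apply_contrast_noise(raw_images[idx], musig[:, 0], musig[:, 1], rng)
            m = len(idx)
            opt.zero_grad()
            mean, logvar = vae.encode(noisy, train=True)
            eps = rng.normal(size=mean.shape)
            std = np.exp(0.5 * logvar)
            z = mean + std * eps
            recon = vae.decode(z, train=True)
            err = recon - clean
            rec_loss = float(np.mean(np.sum(err.reshape(m, -1) ** 2, axis=1)))
            kl = kl_unit_normal(mean, logvar)
            # backward: d(sum-of-squares)/drecon, averaged over batch
            drecon = 2.0 * err / m
            dz = vae.decoder.backward(drecon[:, None])
            dmean = dz + mean / m
            dlogvar = dz * eps * 0.5 * std + 0.5 * (np.exp(logvar) - 1.0) / m
            dfeat = vae.mean_head.backward(dmean) + vae.logvar_head.backward(dlogvar)
            for b in reversed(vae.enc_blocks):
                dfeat = b.backward(dfeat)
            opt.step()
            rec_losses.append(rec_loss)
            kls.append(kl)
        log.append({"epoch": epoch, "recon": float(np.mean(rec_losses)), "kl": float(np.mean(kls))})
    return pd.DataFrame(log)


# ---------------------------------------------------------------------------
# Class Gaussians and the ideal observer


@dataclass
class ClassGaussians:
    """Per-class bivariate Gaussians (means, covariances) with priors."""

    mean_s1: np.ndarray
    mean_s2: np.ndarray
    cov_s1: np.ndarray
    cov_s2: np.ndarray
    prior_s1: float = 0.5

    def __post_init__(self):
        for cov in (self.cov_s1, self.cov_s2):
            cov = np.asarray(cov, dtype=float)
            if not np.allclose(cov, cov.T):
                raise ValueError("covariance must be symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError("covariance must be positive definite")
        if not (0.0 < self.prior_s1 < 1.0):
            raise ValueError("prior must lie in (0, 1)")

    @property
    def prior_s2(self) -> float:
        return 1.0 - self.prior_s1

    @classmethod
    def from_samples(cls, z: np.ndarray, labels: np.ndarray, prior_s1: float = 0.5) -> "ClassGaussians":
        z, labels = np.asarray(z, dtype=float), np.asarray(labels)
        parts = {}
        for lab, key in ((0, "s1"), (1, "s2")):
            zs = z[labels == lab]
            if len(zs) < 3:
                raise ValueError(f"class {key} has fewer than 3 samples")
            parts[key] = (zs.mean(axis=0), np.cov(zs.T))
        return cls(parts["s1"][0], parts["s2"][0], parts["s1"][1], parts["s2"][1], prior_s1)

    def sample(self, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        labels = (rng.random(n) >= self.prior_s1).astype(int)
        z = np.empty((n, 2))
        for lab, mean, cov in ((0, self.mean_s1, self.cov_s1), (1, self.mean_s2, self.cov_s2)):
            idx = np.flatnonzero(labels == lab)
            if idx.size:
                z[idx] = rng.multivariate_normal(mean, cov, size=idx.size)
        return z, labels

    def save(self, path):
        payload = {
            "mean_s1": np.asarray(self.mean_s1).tolist(),
            "mean_s2": np.asarray(self.mean_s2).tolist(),
            "cov_s1": np.asarray(self.cov_s1).tolist(),
            "cov_s2": np.asarray(self.cov_s2).tolist(),
            "prior_s1": self.prior_s1,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["mean_s1"]), np.array(d["mean_s2"]),
            np.array(d["cov_s1"]), np.array(d["cov_s2"]), d["prior_s1"],
        )


def fit_class_gaussians(
    vae: VAE,
    images: np.ndarray,
    labels: np.ndarray,
    use_posterior_means: bool = True,
    batch_size: int = 256,
    rng=None,
) -> ClassGaussians:
    """Embed labelled (processed) images and fit per-class Gaussians to the
    posterior means (default) or to posterior samples."""
    zs = []
    for start in range(0, len(images), batch_size):
        zs.append(vae.embed(images[start : start + batch_size], use_posterior_means, rng=rng))
    return ClassGaussians.from_samples(np.concatenate(zs), labels)


@dataclass
class GeometryStats:
    ratio_s1: float
    ratio_s2: float
    angle_s1: float  # major-axis direction, degrees in [0, 180)
    angle_s2: float
    angle: float  # separation between the major axes as lines, in [0, 90]
    degenerate: bool = False

    @property
    def ratio(self) -> float:
        return 0.5 * (self.ratio_s1 + self.ratio_s2)


def _major_axis(cov: np.ndarray, iso_tol: float = 1e-9) -> tuple[float, float, bool]:
    evals, evecs = np.linalg.eigh(cov)
    ratio = float(np.sqrt(evals[-1] / evals[0]))
    degenerate = (evals[-1] - evals[0]) <= iso_tol * evals[-1]
    v = evecs[:, -1]
    angle = float(np.degrees(np.arctan2(v[1], v[0])) % 180.0)
    return ratio, (0.0 if degenerate else angle), degenerate


def latent_geometry(cg: ClassGaussians) -> GeometryStats:
    """Per-class principal-axis decomposition: the anisotropy ratio is
    sd(major)/sd(minor); the angle is the separation between the two major
    axes, treating each axis as an undirected line in [0, 180)."""
    r1, a1, d1 = _major_axis(np.asarray(cg.cov_s1, dtype=float))
    r2, a2, d2 = _major_axis(np.asarray(cg.cov_s2, dtype=float))
    degenerate = d1 or d2
    # undirected lines: the separation between major axes lives in [0, 90]
    raw = abs(a1 - a2) % 180.0
    angle = 0.0 if degenerate else min(raw, 180.0 - raw)
    if degenerate:
        warnings.warn("isotropic class covariance: axis angle undefined, set to 0", DegenerateGeometryWarning)
    return GeometryStats(r1, r2, a1, a2, angle, degenerate)


def _log_gauss2(z: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = z - mean
    icov = np.linalg.inv(cov)
    _, logdet = np.linalg.slogdet(cov)
    quad = np.einsum("ni,ij,nj->n", diff, icov, diff)
    return -0.5 * (quad + logdet + 2.0 * np.log(2.0 * np.pi))


def io_posterior(cg: ClassGaussians, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class posterior p(y=s1|z), p(y=s2|z) by Bayes' rule."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    l1 = _log_gauss2(z, np.asarray(cg.mean_s1), np.asarray(cg.cov_s1)) + np.log(cg.prior_s1)
    l2 = _log_gauss2(z, np.asarray(cg.mean_s2), np.asarray(cg.cov_s2)) + np.log(cg.prior_s2)
    mx = np.maximum(l1, l2)
    e1, e2 = np.exp(l1 - mx), np.exp(l2 - mx)
    p1 = e1 / (e1 + e2)
    return p1, 1.0 - p1


def io_decide_confidence(cg: ClassGaussians, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decision = argmax posterior (ties -> s1 by convention); confidence =
    max posterior (always >= 0.5 for two classes)."""
    p1, p2 = io_posterior(cg, z)
    decision = (p2 > p1).astype(int)  # tie -> s1 (0)
    confidence = np.maximum(p1, p2)
    return decision, confidence


def io_evaluate_condition(cg_train: ClassGaussians, test_dist, n_mc: int = 20000, seed=0):
    """Monte-Carlo accuracy and mean confidence of the training-distribution
    ideal observer under a test condition.

    ``test_dist`` is either a ClassGaussians (sampled with its priors) or a
    tuple ``(z, labels)`` of latent samples. Returns (accuracy, mean_conf).
    """
    if n_mc < 100:
        warnings.warn("n_mc < 100: Monte-Carlo estimate will be unstable")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if isinstance(test_dist, ClassGaussians):
        z, labels = test_dist.sample(n_mc, rng)
    else:
        z, labels = test_dist
    decision, confidence = io_decide_confidence(cg_train, z)
    return float((decision == labels).mean()), float(confidence.mean())
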