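"""Simulated stimulation and lesions, blindsight, and evidence decoding.

Stimulation ("TMS") is modeled as additive Gaussian noise of variance xi
injected into one layer's activations, after that layer's nonlinearity;
lesions multiply a layer's activations by a scale factor (0.01 for the
blindsight simulation, leaving a trace of the input signal as subcortical
pathways would). A factor of 1 or xi = 0 is an exact no-op.

The decoding analysis trains a bias-free linear probe (sigmoid readout) on
the concatenated activations of all layers (or the penultimate layer
alone) to predict the stimulus class, then splits the probe's evidence by
weight sign into class-specific estimates e_s1 and e_s2, from which ROC /
choice-probability analyses ask whether decisions and confidence track the
balance of evidence or only the response-congruent evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from . import nn
from .networks import ENCODER_BLOCKS, BehavioralRecord, evaluate_trials


@dataclass
class PerturbationSpec:
    """Where and how to perturb: ``layer`` indexes the encoder block
    sequence (0 = first convolutional layer, 5 = the 100-unit penultimate
    layer); ``kind`` is 'additive_noise' (magnitude = noise variance xi) or
    'scale' (magnitude = multiplicative factor)."""

    layer: int
    kind: str
    magnitude: float

    def __post_init__(self):
        if self.kind not in ("additive_noise", "scale"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if not (0 <= self.layer < len(ENCODER_BLOCKS)):
            raise ValueError(f"layer index out of range: {self.layer}")


def make_perturb_fn(spec: PerturbationSpec, rng: np.random.Generator):
    """Build the per-block hook applied after each block's nonlinearity.
    Noise is drawn independently per trial and per unit."""
    def perturb(i, acts):
        if i != spec.layer:
            return acts
        if spec.kind == "scale":
            if spec.magnitude == 1.0:
                return acts
            return acts * spec.magnitude
        if spec.magnitude == 0.0:
            return acts
        return acts + rng.normal(scale=np.sqrt(spec.magnitude), size=acts.shape)

    return perturb


def perturb_forward(net, spec: PerturbationSpec, images, labels, seed, meta=None, store_activations=False) -> BehavioralRecord:
    """Forward pass with one layer perturbed before subsequent layers."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return evaluate_trials(
        net, images, labels, meta=meta, store_activations=store_activations, perturb=make_perturb_fn(spec, rng)
    )


def run_blindsight(
    nets,
    make_test_images,
    contrasts=(0.5, 0.6, 0.7, 0.8, 0.9),
    sigma: float = 4.0,
    factor: float = 0.01,
    n_conf_bins: int = 4,
    seed: int = 0,
    empirical_criterion: bool = True,
) -> pd.DataFrame:
    """First-layer scale lesion on networks trained at high noise, evaluated
    over a contrast sweep against unlesioned controls.

    ``make_test_images(mu, sigma, rng) -> (images, labels)`` builds the
    evaluation stimuli. Both criteria are re-derived from each condition's
    own empirical output distributions: confidence criteria sit at the
    condition's confidence quantiles, and (with ``empirical_criterion``)
    type-1 decisions are read from the median of the decision output rather
    than the fixed 0.5 threshold. A severe lesion shifts the decision
    output by a constant, which would otherwise pin every response to one
    side of the fixed threshold and make d' unmeasurable even though the
    underlying sensitivity is intact; d' itself is criterion-free, so the
    median split recovers it, and a collapsed meta-d' likewise cannot be an
    artifact of a fixed pre-lesion criterion. Returns a tidy table keyed by
    (net, contrast, lesioned) with d', meta-d' and mean confidence.
    """
    from .psychophysics import fit_meta_dprime

    spec = PerturbationSpec(layer=0, kind="scale", magnitude=factor)
    rows = []
    for k, net in enumerate(nets):
        for mu in contrasts:
            rng = np.random.default_rng((seed, k, int(mu * 1000)))
            images, labels = make_test_images(mu, sigma, rng)
            for lesioned in (False, True):
                if lesioned:
                    rec = perturb_forward(net, spec, images, labels, rng)
                else:
                    rec = evaluate_trials(net, images, labels)
                if empirical_criterion and "class_prob" in rec.df:
                    cp = rec.df["class_prob"].to_numpy()
                    dec = (cp > np.median(cp)).astype(int)
                    rec.df["decision"] = dec
                    rec.df["correct"] = dec == rec.df["label"].to_numpy()
                summ = fit_meta_dprime(rec, n_conf_bins)
                rows.append(
                    {
                        "net": k,
                        "contrast": mu,
                        "lesioned": lesioned,
                        "d_prime": summ.d_prime,
                        "meta_d": summ.meta_d_prime,
                        "mean_confidence": float(rec.df["confidence"].mean()),
                        "conf_correct": rec.df.loc[rec.df["correct"], "confidence"].to_numpy(),
                        "conf_incorrect": rec.df.loc[~rec.df["correct"], "confidence"].to_numpy(),
                    }
                )
    return pd.DataFrame(rows)


def overlap_coefficient(a: np.ndarray, b: np.ndarray, n_grid: int = 50) -> float:
    """Distribution overlap of two samples via common-grid histograms:
    1 = identical distributions, 0 = disjoint support."""
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        return 1.0
    edges = np.linspace(lo, hi, n_grid + 1)
    pa, _ = np.histogram(a, bins=edges, density=False)
    pb, _ = np.histogram(b, bins=edges, density=False)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.minimum(pa, pb).sum())


# ---------------------------------------------------------------------------
# Linear probe decoding


def collect_activations(net, images, labels, scope: str = "all_layers") -> np.ndarray:
    rec = evaluate_trials(net, images, labels, store_activations=True)
    return concat_activations(rec.activations, scope), rec


def concat_activations(acts: dict, scope: str) -> np.ndarray:
    if scope == "penultimate":
        return acts["encoder_out"]
    if scope != "all_layers":
        raise ValueError("scope must be 'all_layers' or 'penultimate'")
    return np.concatenate([acts[k] for k in ENCODER_BLOCKS], axis=1)


def train_probe_decoder(
    features: np.ndarray,
    labels: np.ndarray,
    epochs: int = 5,
    lr: float = 5e-4,
    batch_size: int = 32,
    seed: int = 0,
) -> np.ndarray:
    """Train a single bias-free sigmoid layer by gradient descent (Adam,
    cross-entropy) to predict class s2 from concatenated activations.
    Returns the weight vector w."""
    rng = np.random.default_rng(seed)
    n, dim = features.shape
    y = np.asarray(labels, dtype=float)
    w = nn.Param(np.zeros(dim))
    opt = nn.Adam([w], lr=lr)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = features[idx], y[idx]
            p = nn.sigmoid(xb @ w.value)
            opt.zero_grad()
            w.grad += xb.T @ (p - yb) / len(idx)
            opt.step()
    return w.value


@dataclass
class EvidenceEstimates:
    e_s1: np.ndarray
    e_s2: np.ndarray
    weights: np.ndarray
    n_neg: int
    n_pos: int


class DegenerateDecoderError(ValueError):
    """All probe weights share one sign; sign-split evidence is undefined."""


def evidence_estimates(weights: np.ndarray, activations: np.ndarray) -> EvidenceEstimates:
    """Split the probe's evidence by weight sign: e_s1 averages |w| * x over
    negative-weight dimensions, e_s2 averages w * x over positive-weight
    dimensions."""
    w = np.asarray(weights, dtype=float)
    x = np.atleast_2d(np.asarray(activations, dtype=float))
    neg, pos = w < 0, w > 0
    n_neg, n_pos = int(neg.sum()), int(pos.sum())
    if n_neg == 0 or n_pos == 0:
        raise DegenerateDecoderError("probe weights are all one sign")
    e_s1 = (x[:, neg] @ np.abs(w[neg])) / n_neg
    e_s2 = (x[:, pos] @ w[pos]) / n_pos
    return EvidenceEstimates(e_s1, e_s2, w, n_neg, n_pos)


def roc_choice_probability(iv: np.ndarray, dv: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Nonparametric ROC of a scalar variable against a binary outcome.
    Returns (fpr, tpr, choice probability = area under the curve)."""
    dv = np.asarray(dv).astype(int)
    if len(np.unique(dv)) < 2:
        raise ValueError("both outcome classes must be present")
    fpr, tpr, _ = roc_curve(dv, iv)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def decoding_analyses(ev: EvidenceEstimates, record: BehavioralRecord, conf_threshold: float = 0.75) -> dict:
    """The four rule-vs-outcome ROC analyses.

    1. BE -> decision: IV = e_s2 - e_s1, DV = s2 decision.
    2. RCE -> decision: average of the (e_s1, s1-decision) and
       (e_s2, s2-decision) choice probabilities.
    3. BE -> confidence: IV = response-congruent balance (sign flipped for
       s1 decisions), DV = confidence > threshold.
    4. RCE -> confidence: IV = evidence for the chosen class, DV as in 3.
    """
    df = record.df if isinstance(record, BehavioralRecord) else record
    dec = df["decision"].to_numpy()
    conf_hi = df["confidence"].to_numpy() > conf_threshold
    out = {}
    _, _, out["be_decision"] = roc_choice_probability(ev.e_s2 - ev.e_s1, (dec == 1).astype(int))
    cps = []
    for e, target in ((ev.e_s1, dec == 0), (ev.e_s2, dec == 1)):
        _, _, cp = roc_choice_probability(e, target.astype(int))
        cps.append(cp)
    out["rce_decision"] = float(np.mean(cps))
    signed_be = np.where(dec == 0, ev.e_s1 - ev.e_s2, ev.e_s2 - ev.e_s1)
    rce = np.where(dec == 0, ev.e_s1, ev.e_s2)
    if len(np.unique(conf_hi)) < 2:
        out["be_confidence"] = out["rce_confidence"] = np.nan
    else:
        _, _, out["be_confidence"] = roc_choice_probability(signed_be, conf_hi.astype(int))
        _, _, out["rce_confidence"] = roc_choice_probability(rce, conf_hi.astype(int))
    return out
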