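"""Population-geometry and single-unit analyses of penultimate-layer
activations.

The population analysis asks whether decisions and confidence share a
common internal decision variable: principal component analysis of the
trial x neuron activation matrix, sign conventions aligned to behavior
(PC1 positive for s2 trials, PC2 positive for correct trials), and
regressions of the components onto stimulus class, correctness, the
decision output and the confidence output.

The single-unit analysis mirrors classic opt-out electrophysiology: each
neuron is scored by how well it linearly predicts the network's decision
output versus its opt-out output, classified as a decision or confidence
neuron by the sign of dR2 = R2_decision - R2_opt-out, and its preferred
class T_in is the sign of the decision-regression slope. Decision neurons
implicitly encode confidence if their normalized activity orders
T_in-chosen > T_S-chosen (opt-out) > T_opp-chosen trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .networks import BehavioralRecord
from .nn import logit as _logit


@dataclass
class PCAGeometry:
    loadings: np.ndarray  # (n_components, n_neurons)
    variance_fractions: np.ndarray
    scores: np.ndarray  # (n_trials, n_components)

    @property
    def pc1(self) -> np.ndarray:
        return self.scores[:, 0]

    @property
    def pc2(self) -> np.ndarray:
        return self.scores[:, 1]


def pca_geometry(activations: np.ndarray, record: BehavioralRecord | None = None) -> PCAGeometry:
    """Centered PCA of a trial x neuron matrix. When a record is supplied,
    PC1 is oriented so s2 trials score positive on average and PC2 so
    correct trials score positive, making downstream fits reproducible."""
    activations = np.asarray(activations, dtype=float)
    if activations.ndim != 2 or min(activations.shape) < 2:
        raise ValueError("need a trial x neuron matrix with at least 2 of each")
    if np.allclose(activations, activations.mean(axis=0)):
        raise ValueError("rank-0 activations")
    pca = PCA()
    scores = pca.fit_transform(activations)
    loadings = pca.components_
    if record is not None:
        df = record.df if isinstance(record, BehavioralRecord) else record
        signs = np.ones(scores.shape[1])
        s2 = df["label"].to_numpy() == 1
        if 0 < s2.sum() < len(df) and scores[s2, 0].mean() < 0:
            signs[0] = -1
        if scores.shape[1] > 1:
            corr = df["correct"].to_numpy().astype(bool)
            if 0 < corr.sum() < len(df) and scores[corr, 1].mean() < 0:
                signs[1] = -1
        scores = scores * signs
        loadings = loadings * signs[:, None]
    return PCAGeometry(loadings, pca.explained_variance_ratio_, scores)


def _linreg_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Simple-regression R^2 and slope."""
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.slope)


def geometry_regressions(geom: PCAGeometry, record: BehavioralRecord, eps: float = 1e-6) -> dict:
    """Logistic fits (PC1 -> class, PC2 -> correct; reported as prediction
    accuracy) and linear fits (|PC1| -> PC2, PC1 -> logit decision output,
    PC2 -> logit confidence; reported as R^2)."""
    df = record.df if isinstance(record, BehavioralRecord) else record
    if len(np.unique(df["label"])) < 2:
        raise ValueError("degenerate record: a single stimulus class")
    out = {}
    for name, x, y in (
        ("pc1_class_accuracy", geom.pc1, df["label"].to_numpy()),
        ("pc2_correct_accuracy", geom.pc2, df["correct"].to_numpy().astype(int)),
    ):
        if len(np.unique(y)) < 2:
            out[name] = np.nan
            continue
        clf = LogisticRegression(C=1e6)
        clf.fit(x[:, None], y)
        out[name] = float((clf.predict(x[:, None]) == y).mean())
    out["abs_pc1_pc2_r2"], _ = _linreg_r2(np.abs(geom.pc1), geom.pc2)
    if "class_prob" in df:
        out["pc1_decision_r2"], _ = _linreg_r2(geom.pc1, _logit(df["class_prob"].to_numpy(), eps))
    if "p_right" in df:
        out["pc1_decision_r2"], _ = _linreg_r2(geom.pc1, _logit(df["p_right"].to_numpy(), eps))
    out["pc2_confidence_r2"], _ = _linreg_r2(geom.pc2, _logit(df["confidence"].to_numpy(), eps))
    return out


def normalized_activity(activations: np.ndarray, mode: str = "sd") -> np.ndarray:
    """Baseline-referenced normalized activity: subtract each neuron's
    across-trial minimum and divide by the dispersion pooled over all
    neurons and trials (the mean across neurons of each neuron's
    across-trial variance, so that shifting one neuron by a constant
    leaves every normalized value unchanged). ``mode='sd'`` (default)
    divides by the pooled standard deviation, which keeps the measure
    dimensionless; ``mode='variance'`` divides by the pooled variance."""
    x = np.asarray(activations, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    centered = x - x.min(axis=0)
    pooled_var = float(x.var(axis=0).mean())
    if pooled_var <= 0:
        raise ValueError("zero pooled dispersion: all activations identical")
    denom = np.sqrt(pooled_var) if mode == "sd" else pooled_var
    if mode not in ("sd", "variance"):
        raise ValueError("mode must be 'sd' or 'variance'")
    return centered / denom


@dataclass
class UnitStats:
    per_neuron: pd.DataFrame  # r2_decision, r2_opt_out, delta_r2, is_decision, t_in
    condition_means: pd.DataFrame  # per decision neuron: t_in_chosen, t_s_chosen, t_opp_chosen
    t_in_vs_ts: object = None  # paired t-test results across decision neurons
    ts_vs_topp: object = None
    has_opt_out: bool = True


def classify_units_and_tin_analysis(
    activations: np.ndarray,
    record: BehavioralRecord,
    mode: str = "sd",
    eps: float = 1e-6,
) -> UnitStats:
    """Classify penultimate-layer units and test for implicit confidence
    coding in the decision units (RL opt-out task).

    Per neuron: R^2 of linear fits to logit p(s2 action) and to
    logit p(opt-out); decision units have dR2 > 0, with preferred class from
    the decision-fit slope sign. Normalized activity is then averaged per
    choice condition (T_in chosen / T_opp chosen / T_S chosen) and compared
    with paired t-tests across decision units.
    """
    df = record.df if isinstance(record, BehavioralRecord) else record
    x = np.asarray(activations, dtype=float)
    dec_dv = _logit(df["p_right"].to_numpy(), eps)
    opt_dv = _logit(df["p_opt_out"].to_numpy(), eps)
    rows = []
    for j in range(x.shape[1]):
        xj = x[:, j]
        if np.ptp(xj) < 1e-12:
            rows.append({"neuron": j, "r2_decision": 0.0, "r2_opt_out": 0.0, "slope": 0.0})
            continue
        r2d, slope = _linreg_r2(xj, dec_dv)
        r2o, _ = _linreg_r2(xj, opt_dv)
        rows.append({"neuron": j, "r2_decision": r2d, "r2_opt_out": r2o, "slope": slope})
    per = pd.DataFrame(rows)
    per["delta_r2"] = per["r2_decision"] - per["r2_opt_out"]
    per["is_decision"] = per["delta_r2"] > 0
    per["t_in"] = np.where(per["slope"] > 0, 1, 0)  # preferred class: s2 if positive slope

    norm = normalized_activity(x, mode=mode)
    opt_out = df["opt_out"].to_numpy().astype(bool)
    decision = df["decision"].to_numpy()
    has_opt_out = bool(opt_out.any())
    cond_rows = []
    for j in per.loc[per["is_decision"], "neuron"]:
        t_in = per.loc[per["neuron"] == j, "t_in"].iloc[0]
        sel_in = (~opt_out) & (decision == t_in)
        sel_opp = (~opt_out) & (decision != t_in)
        cond_rows.append(
            {
                "neuron": j,
                "t_in_chosen": float(norm[sel_in, j].mean()) if sel_in.any() else np.nan,
                "t_opp_chosen": float(norm[sel_opp, j].mean()) if sel_opp.any() else np.nan,
                "t_s_chosen": float(norm[opt_out, j].mean()) if has_opt_out else np.nan,
            }
        )
    cond = pd.DataFrame(cond_rows)
    t1 = t2 = None
    if has_opt_out and len(cond) > 1:
        ok = cond.dropna()
        if len(ok) > 1:
            t1 = stats.ttest_rel(ok["t_in_chosen"], ok["t_s_chosen"])
            t2 = stats.ttest_rel(ok["t_s_chosen"], ok["t_opp_chosen"])
    return UnitStats(per, cond, t1, t2, has_opt_out)


def rectified_decision_output(class_prob: np.ndarray) -> np.ndarray:
    """Rectify a two-choice decision output p(s2) at 0.5: the probability
    the network assigns to its own decision, max(p, 1-p)."""
    p = np.asarray(class_prob, dtype=float)
    return np.maximum(p, 1.0 - p)
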