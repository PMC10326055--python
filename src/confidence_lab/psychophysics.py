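"""Signal-detection metrics and the behavioral experiment battery.

Type-1 sensitivity d' is the separation, in within-class standard
deviation units, between the two stimulus classes implied by the hit and
false-alarm rates: d' = z(HR) - z(FAR). Type-2 sensitivity meta-d' asks
how well graded confidence discriminates correct from incorrect decisions,
expressed on the same scale as d': it is the d' of an equal-variance SDT
observer whose type-2 (confidence-rating) data would best match the
observed rating counts, holding the relative type-1 criterion fixed. It is
fit here by maximum likelihood over rating counts conditional on stimulus
and response, with response-specific variants fit from one response's
counts only.

The module also hosts the experiment machinery: contrast calibration to a
target accuracy or d', the two positive-evidence-bias comparisons, the
type-1/type-2 dissociation paradigm, and the evidence-grid regression
comparison of confidence rules (balance-of-evidence, response-congruent
evidence, ideal observer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

from .networks import BehavioralRecord
from .nn import logit as _logit
from .nn import sigmoid as _sigmoid

CONF_CLIP_EPS = 1e-6


class CalibrationError(ValueError):
    """Target level unreachable on the searched grid."""


class CalibrationFailure(RuntimeError):
    """Accuracy not balanced between conditions that require it."""


# ---------------------------------------------------------------------------
# Type-1 SDT


def _rates_from_record(df: pd.DataFrame) -> tuple[float, float, int, int]:
    held = ~df["opt_out"].to_numpy() if "opt_out" in df else np.ones(len(df), bool)
    stim = df["label"].to_numpy()[held]
    resp = df["decision"].to_numpy()[held]
    n2 = int((stim == 1).sum())
    n1 = int((stim == 0).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("d' requires at least one trial of each stimulus class")
    hits = int(((stim == 1) & (resp == 1)).sum())
    fas = int(((stim == 0) & (resp == 1)).sum())
    # log-linear correction: pad all cells when any is empty
    if hits in (0, n2) or fas in (0, n1):
        hr = (hits + 0.5) / (n2 + 1.0)
        far = (fas + 0.5) / (n1 + 1.0)
    else:
        hr, far = hits / n2, fas / n1
    return hr, far, n1, n2


def dprime_from_rates(hr: float, far: float) -> tuple[float, float]:
    """d' = z(HR) - z(FAR); criterion c = -(z(HR) + z(FAR)) / 2."""
    zh, zf = ndtri(hr), ndtri(far)
    return float(zh - zf), float(-(zh + zf) / 2.0)


def dprime(record) -> tuple[float, float]:
    """Type-1 d' and criterion from a two-choice record (opt-out trials
    excluded; zero/one cells padded with the log-linear correction)."""
    df = record.df if isinstance(record, BehavioralRecord) else record
    hr, far, _, _ = _rates_from_record(df)
    return dprime_from_rates(hr, far)


# ---------------------------------------------------------------------------
# meta-d'


@dataclass
class SDTSummary:
    d_prime: float
    type1_criterion: float
    meta_d_prime: float = np.nan
    meta_d_s1: float = np.nan
    meta_d_s2: float = np.nan
    confidence_criteria: np.ndarray = field(default=None)
    counts: np.ndarray = field(default=None)  # (stim, resp, rating)
    n_bins: int = 0
    degenerate: bool = False


def bin_confidence(conf: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign ratings 0..n_bins-1 by empirical quantiles of the condition's
    own confidence distribution. Returns (ratings, bin edges)."""
    edges = np.quantile(conf, np.linspace(0, 1, n_bins + 1)[1:-1])
    ratings = np.searchsorted(edges, conf, side="right")
    return ratings, edges


def type2_counts(df: pd.DataFrame, n_bins: int) -> tuple[np.ndarray, np.ndarray, bool]:
    """Rating counts indexed (stimulus, response, rating); confidence
    criteria at the record's empirical quantiles."""
    held = ~df["opt_out"].to_numpy() if "opt_out" in df else np.ones(len(df), bool)
    sub = df.loc[held]
    conf = sub["confidence"].to_numpy()
    degenerate = np.ptp(conf) < 1e-12
    uniq = np.unique(conf)
    if len(uniq) <= n_bins:
        # already-discrete ratings: honor the existing levels
        ratings = np.searchsorted(uniq, conf)
        edges = (uniq[:-1] + uniq[1:]) / 2.0
    else:
        ratings, edges = bin_confidence(conf, n_bins)
    counts = np.zeros((2, 2, n_bins))
    stim, resp = sub["label"].to_numpy(), sub["decision"].to_numpy()
    for s in (0, 1):
        for r in (0, 1):
            sel = (stim == s) & (resp == r)
            counts[s, r] = np.bincount(ratings[sel], minlength=n_bins)
    return counts, edges, degenerate


def _meta_model_probs(meta_d: float, c1rel: float, t2c_s1: np.ndarray, t2c_s2: np.ndarray, n_bins: int):
    """P(response, rating | stimulus) under the equal-variance meta model.

    Stimulus means are -meta_d/2 (s1) and +meta_d/2 (s2); the type-1
    criterion scales with meta_d to preserve the observed relative
    criterion c1rel = c1 / d'.
    """
    c1 = c1rel * meta_d
    means = np.array([-meta_d / 2.0, meta_d / 2.0])
    # boundaries, left to right: rating high->low for s1 resp, low->high for s2
    bounds_s1 = np.concatenate([[-np.inf], t2c_s1, [c1]])
    bounds_s2 = np.concatenate([[c1], t2c_s2, [np.inf]])
    probs = np.zeros((2, 2, n_bins))
    for s in (0, 1):
        cdf1 = ndtr(bounds_s1 - means[s])
        seg1 = np.diff(cdf1)  # leftmost segment = highest rating
        probs[s, 0] = seg1[::-1]
        cdf2 = ndtr(bounds_s2 - means[s])
        probs[s, 1] = np.diff(cdf2)
    return probs


def _fit_meta(counts: np.ndarray, c1rel: float, d_init: float, responses=(0, 1)) -> float:
    """Maximum-likelihood meta-d' from rating counts conditional on
    (stimulus, response), over the given response set."""
    n_bins = counts.shape[2]
    use = np.array(responses)
    cts = counts.copy()
    if (cts[:, use] == 0).any():
        cts = cts + 0.5  # log-linear padding of the type-2 table

    def unpack(theta):
        meta_d = theta[0]
        c1 = c1rel * meta_d
        inc1 = np.exp(np.clip(theta[1:n_bins], -10, 10))
        inc2 = np.exp(np.clip(theta[n_bins : 2 * n_bins - 1], -10, 10))
        t2c_s1 = c1 - np.cumsum(inc1)[::-1]  # ascending, all below c1
        t2c_s2 = c1 + np.cumsum(inc2)
        return meta_d, t2c_s1, t2c_s2

    def nll(theta):
        meta_d, t2c_s1, t2c_s2 = unpack(theta)
        probs = _meta_model_probs(meta_d, c1rel, t2c_s1, t2c_s2, n_bins)
        total = 0.0
        for r in use:
            # conditional on response: normalize within the response region
            pr = probs[:, r] / probs[:, r].sum(axis=1, keepdims=True).clip(1e-300)
            total -= np.sum(cts[:, r] * np.log(pr.clip(1e-300)))
        return total

    theta0 = np.concatenate([[d_init], np.full(2 * (n_bins - 1), np.log(0.4))])
    res = optimize.minimize(nll, theta0, method="Nelder-Mead", options={"maxiter": 4000, "xatol": 1e-5, "fatol": 1e-7})
    return float(res.x[0])


def fit_meta_dprime(record, n_conf_bins: int = 4, response_specific: bool = False) -> SDTSummary:
    """Fit meta-d' (and optionally response-specific meta-d') to a record
    with graded confidence. Confidence criteria are placed at the record's
    empirical quantiles. Records whose confidence is constant carry no
    type-2 information; they are flagged degenerate with meta-d' = NaN."""
    df = record.df if isinstance(record, BehavioralRecord) else record
    hr, far, _, _ = _rates_from_record(df)
    d1, c1 = dprime_from_rates(hr, far)
    counts, edges, degenerate = type2_counts(df, n_conf_bins)
    out = SDTSummary(d1, c1, confidence_criteria=edges, counts=counts, n_bins=n_conf_bins, degenerate=degenerate)
    if degenerate:
        return out
    c1rel = c1 / d1 if abs(d1) > 1e-6 else 0.0
    out.meta_d_prime = _fit_meta(counts, c1rel, d1)
    if response_specific:
        out.meta_d_s1 = _fit_meta(counts, c1rel, d1, responses=(0,))
        out.meta_d_s2 = _fit_meta(counts, c1rel, d1, responses=(1,))
    return out


def simulate_sdt_observer(d_prime: float, n: int, seed, meta_d: float | None = None, n_bins: int = 4) -> pd.DataFrame:
    """Forward-simulate an equal-variance SDT observer (criterion 0).

    With ``meta_d=None`` confidence is the ideal type-2 readout: the
    posterior probability of the chosen response, sigmoid(d' |x|), a
    monotone function of the decision variable's distance from the
    criterion. Otherwise type-1 responses come from ``d_prime`` and rating
    counts are drawn from the meta model at ``meta_d`` with equally spaced
    type-2 criteria.
    """
    rng = np.random.default_rng(seed)
    stim = rng.integers(0, 2, size=n)
    x = rng.normal(size=n) + (stim - 0.5) * d_prime
    resp = (x > 0).astype(int)
    if meta_d is None:
        conf = _sigmoid(max(d_prime, 1e-6) * np.abs(x))
    else:
        spacing = 0.5 * max(meta_d, 0.5)
        t2c_s1 = -spacing * np.arange(n_bins - 1, 0, -1)
        t2c_s2 = spacing * np.arange(1, n_bins)
        probs = _meta_model_probs(meta_d, 0.0, t2c_s1, t2c_s2, n_bins)
        conf = np.empty(n)
        for s in (0, 1):
            for r in (0, 1):
                sel = (stim == s) & (resp == r)
                p = probs[s, r] / probs[s, r].sum()
                conf[sel] = rng.choice(n_bins, size=sel.sum(), p=p)
    return pd.DataFrame(
        {"label": stim, "decision": resp, "confidence": conf, "opt_out": False, "correct": stim == resp}
    )


# ---------------------------------------------------------------------------
# Type-2 noise


def add_type2_noise(record, xi: float, seed) -> BehavioralRecord:
    """Perturb confidence with late (post-decisional) noise: map through the
    logit, add Gaussian noise of variance xi, and map back through the
    sigmoid. Confidence is clipped to [eps, 1-eps] before the logit."""
    if xi < 0:
        raise ValueError("xi must be non-negative")
    df = (record.df if isinstance(record, BehavioralRecord) else record).copy()
    if xi > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        noise = rng.normal(scale=np.sqrt(xi), size=len(df))
        df["confidence"] = _sigmoid(_logit(df["confidence"].to_numpy(), CONF_CLIP_EPS) + noise)
    acts = record.activations if isinstance(record, BehavioralRecord) else {}
    return BehavioralRecord(df, acts)


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class CalibrationResult:
    target_level: float
    fitted_value: float
    grid: np.ndarray
    grid_values: np.ndarray
    at_boundary: bool = False


def calibrate_contrast(evaluate, target_level: float, grid) -> CalibrationResult:
    """Sweep ``evaluate(mu)`` over a contrast grid and linearly interpolate
    the contrast achieving the target level (accuracy or d').

    The response is checked for an overall increasing trend. A target below
    the entire curve returns the minimal grid contrast with a warning (the
    chance floor); a target above the curve is unreachable and raises.
    """
    grid = np.asarray(grid, dtype=float)
    vals = np.array([evaluate(mu) for mu in grid])
    if stats.spearmanr(grid, vals).statistic <= 0:
        warnings.warn("evaluator is not increasing in contrast over the grid")
    if target_level > vals.max():
        raise CalibrationError(f"target {target_level} above achievable range (max {vals.max():.3f})")
    if target_level <= vals.min():
        warnings.warn("target at or below the grid floor; returning minimal contrast")
        return CalibrationResult(target_level, float(grid[0]), grid, vals, at_boundary=True)
    # first upward crossing of the target
    above = np.flatnonzero(vals >= target_level)
    j = above[0]
    if j == 0:
        return CalibrationResult(target_level, float(grid[0]), grid, vals, at_boundary=True)
    x0, x1, y0, y1 = grid[j - 1], grid[j], vals[j - 1], vals[j]
    mu = x0 + (target_level - y0) * (x1 - x0) / max(y1 - y0, 1e-12)
    return CalibrationResult(target_level, float(mu), grid, vals)


# ---------------------------------------------------------------------------
# PE bias comparisons


def _condition_summary(rec: BehavioralRecord, use_opt_out_rate: bool) -> tuple[float, float]:
    acc = rec.accuracy
    if use_opt_out_rate:
        conf = float(rec.df["opt_out"].mean())
    else:
        conf = float(rec.df.loc[~rec.df["opt_out"], "confidence"].mean())
    return acc, conf


def compare_conditions(
    nets: list,
    evaluate_condition,
    condition_a: dict,
    condition_b: dict,
    seed: int = 0,
    use_opt_out_rate: bool = False,
    accuracy_tol: float | None = None,
    strict: bool = True,
) -> dict:
    """Evaluate every network under two conditions and compare accuracy and
    the confidence measure (mean confidence, or opt-out rate for the RL
    task) with paired t-tests.

    The accuracy-balance gate runs before any confidence comparison: the
    absolute mean paired accuracy difference must not exceed
    ``accuracy_tol`` (default: the larger of 1 percentage point and twice
    the standard error of the paired difference).
    """
    rows = []
    for i, net in enumerate(nets):
        rng = np.random.default_rng((seed, i))
        rec_a = evaluate_condition(net, rng=rng, **condition_a)
        rec_b = evaluate_condition(net, rng=rng, **condition_b)
        acc_a, conf_a = _condition_summary(rec_a, use_opt_out_rate)
        acc_b, conf_b = _condition_summary(rec_b, use_opt_out_rate)
        rows.append({"net": i, "acc_a": acc_a, "acc_b": acc_b, "conf_a": conf_a, "conf_b": conf_b})
    df = pd.DataFrame(rows)
    d_acc = df["acc_b"] - df["acc_a"]
    d_conf = df["conf_b"] - df["conf_a"]
    tol = accuracy_tol
    if tol is None:
        sem = float(d_acc.sem()) if len(df) > 1 else 0.0
        tol = max(0.01, 2.0 * sem)
    balanced = abs(float(d_acc.mean())) <= tol
    if strict and not balanced:
        raise CalibrationFailure(
            f"accuracy gap {float(d_acc.mean()):.3f} exceeds tolerance {tol:.3f}; recalibrate contrasts"
        )
    t_acc = stats.ttest_rel(df["acc_b"], df["acc_a"]) if len(df) > 1 else None
    t_conf = stats.ttest_rel(df["conf_b"], df["conf_a"]) if len(df) > 1 else None
    return {
        "per_net": df,
        "accuracy_diff": float(d_acc.mean()),
        "confidence_diff": float(d_conf.mean()),
        "accuracy_balanced": balanced,
        "accuracy_tol": tol,
        "t_accuracy": t_acc,
        "t_confidence": t_conf,
        "confidence_measure": "opt_out_rate" if use_opt_out_rate else "confidence",
    }


def pe_bias_v1(nets, evaluate_condition, low_pe: tuple, high_pe: tuple, **kwargs) -> dict:
    """Positive-evidence bias, version 1: low signal/low noise vs high
    signal/high noise at matched accuracy. Conditions are (mu, sigma) pairs;
    a positive ``confidence_diff`` means higher confidence (or opt-out rate)
    in the high-PE condition."""
    out = compare_conditions(
        nets,
        evaluate_condition,
        {"mu": low_pe[0], "sigma": low_pe[1]},
        {"mu": high_pe[0], "sigma": high_pe[1]},
        **kwargs,
    )
    out["low_pe"], out["high_pe"] = low_pe, high_pe
    return out


def pe_bias_v2(
    nets,
    evaluate_superimposed,
    nontarget_low: float,
    nontarget_high: float,
    sigma: float,
    mu_target_low: float = 0.5,
    mu_target_high: float = 1.0,
    **kwargs,
) -> dict:
    """Positive-evidence bias, version 2: superimposed stimuli where the task
    is to report the higher-contrast class. Low PE: target 0.5; high PE:
    target 1.0; nontarget contrasts are pre-calibrated for matched accuracy."""
    if nontarget_low >= mu_target_low or nontarget_high >= mu_target_high:
        raise ValueError("nontarget contrast must be below the target contrast")
    out = compare_conditions(
        nets,
        evaluate_superimposed,
        {"mu_target": mu_target_low, "mu_nontarget": nontarget_low, "sigma": sigma},
        {"mu_target": mu_target_high, "mu_nontarget": nontarget_high, "sigma": sigma},
        **kwargs,
    )
    out["conditions"] = {
        "low": (mu_target_low, nontarget_low),
        "high": (mu_target_high, nontarget_high),
        "sigma": sigma,
    }
    return out


# ---------------------------------------------------------------------------
# Type-1 / type-2 dissociation


def type1_type2_dissociation(
    nets,
    evaluate_pair,
    target_dprimes=(0.5, 1.0, 1.5, 2.0, 2.5),
    sigma: float = 2.0,
    xi: float | None = 1.2,
    xi_grid=None,
    target_meta_pattern=None,
    mu3_grid=None,
    s2_grid=None,
    n_conf_bins: int = 4,
    seed: int = 0,
    auto_scale_targets: bool = False,
) -> dict:
    """Five-condition paradigm: s1 is always shown at the intermediate
    contrast mu_3 while the s2 contrast sweeps across conditions so that
    average d' hits the five targets. Type-2 noise of variance xi is applied
    to confidence before the meta-d' fits (or fit by grid search against
    ``target_meta_pattern`` when given)."""
    rng = np.random.default_rng(seed)
    mu3_grid = np.linspace(0.15, 0.8, 14) if mu3_grid is None else np.asarray(mu3_grid)
    s2_grid = np.linspace(0.02, 1.0, 25) if s2_grid is None else np.asarray(s2_grid)

    target_dprimes = list(target_dprimes)

    def avg_dprime_same(mu):
        ds = [dprime(evaluate_pair(net, mu_s1=mu, mu_s2=mu, sigma=sigma, rng=np.random.default_rng((seed, 1, k))))[0] for k, net in enumerate(nets)]
        return float(np.mean(ds))

    same_vals = np.array([avg_dprime_same(m) for m in mu3_grid])
    mid_target = target_dprimes[2]
    if auto_scale_targets and mid_target > 0.8 * same_vals.max():
        mid_target = 0.8 * float(same_vals.max())

    def interp_crossing(grid_x, grid_y, target):
        above = np.flatnonzero(grid_y >= target)
        if len(above) == 0:
            raise CalibrationError(f"target d' {target} unreachable")
        j = above[0]
        if j == 0:
            return float(grid_x[0])
        x0, x1, y0, y1 = grid_x[j - 1], grid_x[j], grid_y[j - 1], grid_y[j]
        return float(x0 + (target - y0) * (x1 - x0) / max(y1 - y0, 1e-12))

    mu3 = interp_crossing(mu3_grid, same_vals, mid_target)

    def avg_dprime_s2(mu_s2):
        ds = [dprime(evaluate_pair(net, mu_s1=mu3, mu_s2=mu_s2, sigma=sigma, rng=np.random.default_rng((seed, 2, k))))[0] for k, net in enumerate(nets)]
        return float(np.mean(ds))

    sweep_vals = np.array([avg_dprime_s2(m) for m in s2_grid])
    if auto_scale_targets:
        lo = max(float(sweep_vals.min()) + 0.1, 0.2)
        hi = 0.92 * float(sweep_vals.max())
        if hi > lo:
            target_dprimes = list(np.linspace(lo, hi, len(target_dprimes)))
    mu_conditions = []
    for i, target in enumerate(target_dprimes):
        if i == 2 and not auto_scale_targets:
            mu_conditions.append(mu3)
            continue
        mu_conditions.append(interp_crossing(s2_grid, sweep_vals, target))

    records = [
        [evaluate_pair(net, mu_s1=mu3, mu_s2=mu_c, sigma=sigma, rng=np.random.default_rng((seed, 3, k, c))) for c, mu_c in enumerate(mu_conditions)]
        for k, net in enumerate(nets)
    ]

    if target_meta_pattern is not None:
        xi_grid = np.linspace(0.1, 2.0, 20) if xi_grid is None else np.asarray(xi_grid)
        best, best_err = xi_grid[0], np.inf
        for cand in xi_grid:
            metas = []
            for c in range(len(mu_conditions)):
                vals = [
                    fit_meta_dprime(add_type2_noise(records[k][c], cand, (seed, 4, k, c)), n_conf_bins).meta_d_prime
                    for k in range(len(nets))
                ]
                metas.append(np.nanmean(vals))
            err = float(np.mean((np.asarray(metas) - np.asarray(target_meta_pattern)) ** 2))
            if err < best_err:
                best, best_err = float(cand), err
        xi = best

    rows = []
    for k in range(len(nets)):
        for c, mu_c in enumerate(mu_conditions):
            rec = records[k][c] if not xi else add_type2_noise(records[k][c], xi, (seed, 5, k, c))
            summ = fit_meta_dprime(rec, n_conf_bins, response_specific=True)
            rows.append(
                {
                    "net": k,
                    "condition": c,
                    "mu_s2": mu_c,
                    "d_prime": summ.d_prime,
                    "meta_d": summ.meta_d_prime,
                    "meta_d_s1": summ.meta_d_s1,
                    "meta_d_s2": summ.meta_d_s2,
                }
            )
    return {"per_net": pd.DataFrame(rows), "mu3": mu3, "mu_conditions": mu_conditions, "xi": xi}


# ---------------------------------------------------------------------------
# Evidence-grid analysis


@dataclass
class GridResult:
    """Per-cell behavior over the (mu_s1, mu_s2) evidence grid."""

    df: pd.DataFrame  # columns: mu_s1, mu_s2, accuracy, confidence, rce

    @property
    def n_cells(self) -> int:
        return len(self.df)


def evidence_grid(
    net,
    evaluate_superimposed_cell,
    grid_n: int = 100,
    mu_range=(0.1, 1.0),
    sigma: float = 1.5,
    seed: int = 0,
) -> GridResult:
    """Evaluate one network over the full grid of (mu_s1, mu_s2) contrast
    combinations (grid_n x grid_n cells). The evaluator returns a record for
    a cell; correctness means reporting the higher-contrast class."""
    mus = np.linspace(mu_range[0], mu_range[1], grid_n)
    rows = []
    rng = np.random.default_rng(seed)
    for m1 in mus:
        for m2 in mus:
            rec = evaluate_superimposed_cell(net, mu_s1=m1, mu_s2=m2, sigma=sigma, rng=rng)
            dec = rec.df["decision"].to_numpy()
            rce = np.where(dec == 0, m1, m2)
            rows.append(
                {
                    "mu_s1": m1,
                    "mu_s2": m2,
                    "accuracy": rec.accuracy,
                    "confidence": float(rec.df["confidence"].mean()),
                    "rce": float(rce.mean()),
                }
            )
    return GridResult(pd.DataFrame(rows))


def _ols_r2(x: np.ndarray, y: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid**2).sum()) / max(ss_tot, 1e-300)


def confidence_regressions(grids: list[GridResult], io_confidence: np.ndarray | None = None) -> pd.DataFrame:
    """Compare confidence rules as linear predictors of each network's
    per-cell mean confidence: BE = mu_s2 - mu_s1, RCE = contrast of the
    chosen class (cell mean), and optionally the ideal-observer confidence
    surface. Each model may use a logit transform of confidence as the
    dependent variable; the better-fitting version is kept per model. The
    noise ceiling uses the leave-one-out mean surface across networks as
    the predictor (requires >= 2 networks)."""
    if len(grids) == 0:
        raise ValueError("no grids")
    conf_all = np.stack([g.df["confidence"].to_numpy() for g in grids])
    rows = []
    for i, g in enumerate(grids):
        conf = conf_all[i]
        conf_logit = _logit(conf, CONF_CLIP_EPS)
        preds = {
            "be": g.df["mu_s2"].to_numpy() - g.df["mu_s1"].to_numpy(),
            "rce": g.df["rce"].to_numpy(),
        }
        if io_confidence is not None:
            preds["ideal_observer"] = np.asarray(io_confidence)
        if len(grids) > 1:
            preds["noise_ceiling"] = conf_all[np.arange(len(grids)) != i].mean(axis=0)
        row = {"net": i}
        for name, x in preds.items():
            r2_raw = _ols_r2(x, conf)
            r2_log = _ols_r2(x, conf_logit)
            row[name] = max(r2_raw, r2_log)
            row[f"{name}_used_logit"] = bool(r2_log > r2_raw)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(grids) < 2:
        out.attrs["noise_ceiling_unavailable"] = True
    return out
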