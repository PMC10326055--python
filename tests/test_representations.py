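"""Population geometry and single-unit analyses."""

import numpy as np
import pandas as pd
import pytest

from confidence_lab import representations as R
from confidence_lab.networks import BehavioralRecord
from confidence_lab.nn import logit, sigmoid


def make_record(n, rng, p_right=None, p_opt_out=None, labels=None, confidence=None):
    labels = rng.integers(0, 2, n) if labels is None else labels
    p_right = rng.random(n) if p_right is None else p_right
    p_opt_out = np.full(n, 0.2) if p_opt_out is None else p_opt_out
    decision = (p_right >= 0.5).astype(int)
    opt_out = p_opt_out > 0.5
    conf = 1.0 - p_opt_out if confidence is None else confidence
    return BehavioralRecord(
        pd.DataFrame(
            {
                "label": labels,
                "decision": decision,
                "confidence": conf,
                "opt_out": opt_out,
                "correct": decision == labels,
                "p_right": p_right,
                "p_opt_out": p_opt_out,
                "class_prob": p_right,
            }
        )
    )


class TestPCAGeometry:
    def test_variance_fractions_sum_to_one(self, rng):
        acts = rng.normal(size=(200, 20))
        geom = R.pca_geometry(acts)
        assert geom.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constructed_rank_two_data(self, rng):
        u = rng.normal(size=20)
        v = rng.normal(size=20)
        coef = rng.normal(size=(300, 2))
        acts = coef[:, :1] * u + coef[:, 1:] * v + 1e-3 * rng.normal(size=(300, 20))
        geom = R.pca_geometry(acts)
        assert geom.variance_fractions[:2].sum() > 0.999

    def test_neuron_permutation_leaves_scores(self, rng):
        acts = rng.normal(size=(100, 12))
        perm = rng.permutation(12)
        a = R.pca_geometry(acts)
        b = R.pca_geometry(acts[:, perm])
        # scores match up to per-component sign
        for k in range(3):
            assert min(
                np.abs(a.scores[:, k] - b.scores[:, k]).max(),
                np.abs(a.scores[:, k] + b.scores[:, k]).max(),
            ) < 1e-8

    def test_sign_convention_alignment(self, rng):
        n = 400
        labels = rng.integers(0, 2, n)
        signal = (labels * 2 - 1) + 0.3 * rng.normal(size=n)
        acts = np.outer(signal, rng.normal(size=15)) + 0.01 * rng.normal(size=(n, 15))
        rec = make_record(n, rng, p_right=sigmoid(signal), labels=labels)
        geom = R.pca_geometry(acts, record=rec)
        assert geom.pc1[labels == 1].mean() > 0

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError):
            R.pca_geometry(np.ones((50, 5)))


class TestGeometryRegressions:
    def test_identical_dv_gives_unit_r2(self, rng):
        n = 300
        labels = rng.integers(0, 2, n)
        # signed evidence with a broad magnitude spread, so |signal| carries
        # substantial variance of its own
        signal = (labels * 2 - 1) * rng.uniform(0.5, 2.5, size=n)
        # embed signal and |signal| along orthogonal directions with the
        # signal direction dominant, so PC1 = signal and PC2 = |signal|
        basis, _ = np.linalg.qr(rng.normal(size=(10, 2)))
        acts = 3.0 * np.outer(signal, basis[:, 0]) + np.outer(np.abs(signal), basis[:, 1])
        acts += 1e-4 * rng.normal(size=acts.shape)
        rec = make_record(n, rng, p_right=sigmoid(signal), labels=labels)
        geom = R.pca_geometry(acts, record=rec)
        out = R.geometry_regressions(geom, rec)
        # decision output is a monotone function of PC1 by construction
        assert out["pc1_decision_r2"] > 0.99
        assert out["abs_pc1_pc2_r2"] > 0.95

    def test_separable_logistic_case(self, rng):
        n = 200
        labels = np.repeat([0, 1], n // 2)
        acts = np.column_stack([(labels * 2 - 1) * 3.0, rng.normal(size=n) * 1e-2])
        acts = acts @ rng.normal(size=(2, 8)) + 1e-6 * rng.normal(size=(n, 8))
        rec = make_record(n, rng, p_right=sigmoid((labels * 2 - 1) * 3.0), labels=labels)
        geom = R.pca_geometry(acts, record=rec)
        out = R.geometry_regressions(geom, rec)
        assert out["pc1_class_accuracy"] == 1.0

    def test_single_class_rejected(self, rng):
        rec = make_record(50, rng, labels=np.zeros(50, dtype=int))
        geom = R.pca_geometry(rng.normal(size=(50, 5)))
        with pytest.raises(ValueError):
            R.geometry_regressions(geom, rec)


class TestNormalizedActivity:
    def test_matches_bruteforce_oracle(self):
        x = np.array([[1.0, 5.0], [3.0, 2.0], [2.0, 8.0]])  # 3 trials, 2 neurons
        # independent elementwise oracle: subtract column min, divide by the
        # pooled dispersion (mean of per-neuron variances, then sqrt)
        pooled_var = np.mean([np.var(x[:, j]) for j in range(2)])
        pooled_sd = np.sqrt(pooled_var)
        expected = np.empty_like(x)
        for j in range(2):
            for i in range(3):
                expected[i, j] = (x[i, j] - x[:, j].min()) / pooled_sd
        assert np.allclose(R.normalized_activity(x, mode="sd"), expected)
        # literal-variance mode divides by the pooled variance instead
        assert np.allclose(R.normalized_activity(x, mode="variance"), expected * pooled_sd / pooled_var)

    def test_minimum_trial_maps_to_zero(self, rng):
        x = rng.normal(size=(20, 6))
        norm = R.normalized_activity(x)
        assert np.allclose(norm.min(axis=0), 0.0)

    def test_constant_neuron_all_zero(self, rng):
        x = rng.normal(size=(10, 3))
        x[:, 1] = 4.2
        norm = R.normalized_activity(x)
        assert np.allclose(norm[:, 1], 0.0)

    def test_translation_invariance_per_neuron(self, rng):
        x = rng.normal(size=(30, 4))
        shifted = x.copy()
        shifted[:, 2] += 7.5
        a = R.normalized_activity(x)
        # pooled dispersion changes only through the shifted neuron's variance,
        # which translation leaves intact
        b = R.normalized_activity(shifted)
        assert np.allclose(a, b)

    def test_zero_dispersion_rejected(self):
        with pytest.raises(ValueError):
            R.normalized_activity(np.full((5, 3), 2.0))


class TestSingleUnitClassification:
    def test_constructed_decision_units_detected(self, rng):
        n = 2000
        dv = rng.normal(size=n)
        p_right = sigmoid(2.0 * dv)
        p_opt = sigmoid(rng.normal(size=n) - 1.5)
        rec = make_record(n, rng, p_right=p_right, p_opt_out=p_opt)
        # neurons 0-2 code the decision variable, neurons 3-4 the opt-out
        acts = np.column_stack(
            [
                dv + 0.05 * rng.normal(size=n),
                -dv + 0.05 * rng.normal(size=n),
                0.5 * dv + 0.05 * rng.normal(size=n),
                logit(p_opt) + 0.05 * rng.normal(size=n),
                logit(p_opt) * 0.7 + 0.05 * rng.normal(size=n),
            ]
        )
        stats = R.classify_units_and_tin_analysis(acts, rec)
        per = stats.per_neuron
        assert per.loc[:2, "is_decision"].all()
        assert not per.loc[3:, "is_decision"].any()
        assert (per.loc[:2, "r2_decision"] > 0.9).all()
        assert (per.loc[:2, "r2_opt_out"] < 0.1).all()
        # preferred class follows the slope sign
        assert per.loc[0, "t_in"] == 1 and per.loc[1, "t_in"] == 0

    def test_delta_r2_partitions_units(self, rng):
        n = 500
        rec = make_record(n, rng)
        acts = rng.normal(size=(n, 8))
        stats = R.classify_units_and_tin_analysis(acts, rec)
        per = stats.per_neuron
        assert ((per["delta_r2"] > 0) == per["is_decision"]).all()

    def test_no_opt_out_trials_flagged(self, rng):
        n = 300
        rec = make_record(n, rng, p_opt_out=np.full(n, 0.05))
        stats = R.classify_units_and_tin_analysis(rng.normal(size=(n, 6)), rec)
        assert not stats.has_opt_out
        assert stats.t_in_vs_ts is None


def test_rectified_decision_output():
    p = np.array([0.1, 0.5, 0.8])
    assert np.allclose(R.rectified_decision_output(p), [0.9, 0.5, 0.8])
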