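"""SDT metrics, meta-d' estimation, calibration, and experiment machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri
from scipy.stats import norm

from confidence_lab import psychophysics as P


class TestDprime:
    def test_equal_rates_give_zero(self):
        df = pd.DataFrame(
            {
                "label": [0, 0, 1, 1] * 10,
                "decision": [0, 1, 0, 1] * 10,
                "opt_out": False,
                "confidence": 0.7,
            }
        )
        d, c = P.dprime(df)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_textbook_rates(self):
        # z(0.84) - z(0.16): double inverse-normal oracle
        d, _ = P.dprime_from_rates(0.84, 0.16)
        assert d == pytest.approx(ndtri(0.84) - ndtri(0.16))
        assert d == pytest.approx(1.989, abs=1e-3)

    def test_perfect_hit_rate_stays_finite(self):
        df = pd.DataFrame(
            {
                "label": [1] * 20 + [0] * 20,
                "decision": [1] * 20 + [0] * 10 + [1] * 10,
                "opt_out": False,
                "confidence": 0.5,
            }
        )
        d, _ = P.dprime(df)
        assert np.isfinite(d)

    def test_single_stimulus_rejected(self):
        df = pd.DataFrame({"label": [1] * 5, "decision": [1] * 5, "opt_out": False, "confidence": 0.5})
        with pytest.raises(ValueError):
            P.dprime(df)


class TestMetaDprime:
    def test_ideal_observer_meta_equals_d(self):
        # confidence = |decision variable|: theoretical meta-d' = d'
        df = P.simulate_sdt_observer(2.0, 100_000, seed=1)
        s = P.fit_meta_dprime(df, 4, response_specific=True)
        assert s.meta_d_prime == pytest.approx(2.0, abs=0.1)
        assert s.meta_d_s1 == pytest.approx(2.0, abs=0.15)
        assert s.meta_d_s2 == pytest.approx(2.0, abs=0.15)

    def test_forward_model_inversion(self):
        df = P.simulate_sdt_observer(2.0, 100_000, seed=2, meta_d=1.0)
        s = P.fit_meta_dprime(df, 4)
        assert s.d_prime == pytest.approx(2.0, abs=0.05)
        assert s.meta_d_prime == pytest.approx(1.0, abs=0.1)

    def test_independent_confidence_gives_zero_meta(self):
        df = P.simulate_sdt_observer(2.0, 50_000, seed=3)
        rng = np.random.default_rng(0)
        df["confidence"] = rng.permutation(df["confidence"].to_numpy())
        s = P.fit_meta_dprime(df, 4)
        assert abs(s.meta_d_prime) < 0.1

    def test_constant_confidence_flagged_degenerate(self):
        df = P.simulate_sdt_observer(1.5, 2_000, seed=4)
        df["confidence"] = 0.8
        s = P.fit_meta_dprime(df, 4)
        assert s.degenerate and np.isnan(s.meta_d_prime)

    def test_recovery_grid_median_error(self):
        # 3x3 grid of (d', meta ratio) at n=1e5: median |error| < 0.1
        errs = []
        for d in (1.0, 1.5, 2.0):
            for ratio in (0.5, 0.75, 1.0):
                df = P.simulate_sdt_observer(d, 100_000, seed=hash((d, ratio)) % 1000, meta_d=d * ratio)
                errs.append(abs(P.fit_meta_dprime(df, 4).meta_d_prime - d * ratio))
        assert np.median(errs) < 0.1


class TestType2Noise:
    def test_zero_noise_is_identity(self):
        df = P.simulate_sdt_observer(1.0, 500, seed=5)
        out = P.add_type2_noise(df, 0.0, seed=0)
        assert np.array_equal(out.df["confidence"].to_numpy(), df["confidence"].to_numpy())

    def test_outputs_stay_in_unit_interval(self):
        df = P.simulate_sdt_observer(1.0, 2_000, seed=6)
        out = P.add_type2_noise(df, 4.0, seed=1)
        conf = out.df["confidence"].to_numpy()
        assert conf.min() >= 0.0 and conf.max() <= 1.0

    def test_negative_variance_rejected(self):
        df = P.simulate_sdt_observer(1.0, 100, seed=7)
        with pytest.raises(ValueError):
            P.add_type2_noise(df, -0.5, seed=0)

    def test_meta_d_degrades_with_noise(self):
        # expected meta-d' non-increasing across a 5-point noise sweep
        base = P.simulate_sdt_observer(2.0, 20_000, seed=8)
        xis = (0.0, 0.5, 1.0, 2.0, 4.0)
        means = []
        for xi in xis:
            vals = [
                P.fit_meta_dprime(P.add_type2_noise(base, xi, seed=(9, rep)), 4).meta_d_prime
                for rep in range(20)
            ]
            means.append(np.mean(vals))
        from scipy.stats import spearmanr

        assert spearmanr(xis, means).statistic < 0
        assert all(b <= a + 0.05 for a, b in zip(means, means[1:]))
        assert means[-1] < means[0] - 0.5


class TestCalibration:
    def test_closed_form_psychometric_inversion(self):
        # accuracy(mu) = Phi(2 mu); target 0.75 inverts to ~0.337
        cal = P.calibrate_contrast(lambda mu: norm.cdf(2 * mu), 0.75, np.linspace(0, 1, 101))
        assert cal.fitted_value == pytest.approx(ndtri(0.75) / 2, abs=0.01)

    def test_chance_target_returns_floor_with_warning(self):
        with pytest.warns(UserWarning, match="floor"):
            cal = P.calibrate_contrast(lambda mu: 0.5 + 0.4 * mu, 0.5, np.linspace(0.1, 1, 10))
        assert cal.fitted_value == pytest.approx(0.1)
        assert cal.at_boundary

    def test_unreachable_target_raises(self):
        with pytest.raises(P.CalibrationError):
            P.calibrate_contrast(lambda mu: 0.5 + 0.1 * mu, 0.99, np.linspace(0, 1, 10))


class FakeNet:
    """Deterministic stand-in observer for condition-comparison plumbing."""

    def __init__(self, conf_gain=1.0):
        self.conf_gain = conf_gain


def fake_evaluate(net, mu, sigma, rng, n=400):
    from confidence_lab.networks import BehavioralRecord

    snr = mu / sigma
    label = rng.integers(0, 2, n)
    correct = rng.random(n) < norm.cdf(2 * snr)
    decision = np.where(correct, label, 1 - label)
    conf = np.clip(0.5 + net.conf_gain * snr + rng.normal(0, 0.05, n), 0, 1)
    return BehavioralRecord(
        pd.DataFrame(
            {"label": label, "decision": decision, "correct": correct, "confidence": conf, "opt_out": False}
        )
    )


class TestConditionComparison:
    def test_identical_conditions_zero_difference(self):
        nets = [FakeNet(), FakeNet()]
        out = P.compare_conditions(
            nets, fake_evaluate, {"mu": 0.4, "sigma": 1.0}, {"mu": 0.4, "sigma": 1.0}, seed=1
        )
        assert abs(out["confidence_diff"]) < 0.02
        assert out["accuracy_balanced"]

    def test_unbalanced_accuracy_trips_gate(self):
        nets = [FakeNet(), FakeNet(), FakeNet()]
        with pytest.raises(P.CalibrationFailure):
            P.compare_conditions(
                nets, fake_evaluate, {"mu": 0.1, "sigma": 1.0}, {"mu": 0.9, "sigma": 1.0}, seed=1
            )

    def test_pe_bias_v2_rejects_inverted_contrasts(self):
        with pytest.raises(ValueError):
            P.pe_bias_v2([FakeNet()], fake_evaluate, nontarget_low=0.6, nontarget_high=0.7, sigma=1.0)


class TestEvidenceGridRegressions:
    @staticmethod
    def make_grids(conf_rule, n_nets=3, grid_n=10, noise=0.0):
        rng = np.random.default_rng(11)
        mus = np.linspace(0.1, 1.0, grid_n)
        grids = []
        for _ in range(n_nets):
            rows = []
            for m1 in mus:
                for m2 in mus:
                    dec = int(m2 > m1)
                    rce = m1 if dec == 0 else m2
                    conf = conf_rule(m1, m2, rce) + noise * rng.normal()
                    rows.append(
                        {"mu_s1": m1, "mu_s2": m2, "accuracy": 0.75, "confidence": conf, "rce": rce}
                    )
            grids.append(P.GridResult(pd.DataFrame(rows)))
        return grids

    def test_grid_covers_all_combinations(self):
        grids = self.make_grids(lambda m1, m2, rce: 0.5, n_nets=1, grid_n=10)
        assert grids[0].n_cells == 100

    def test_exact_rce_confidence_gives_unit_r2(self):
        grids = self.make_grids(lambda m1, m2, rce: 0.2 + 0.6 * rce)
        fits = P.confidence_regressions(grids)
        assert np.allclose(fits["rce"], 1.0, atol=1e-9)

    def test_be_generated_confidence_prefers_be(self):
        grids = self.make_grids(lambda m1, m2, rce: 0.5 + 0.3 * (m2 - m1), noise=0.02)
        fits = P.confidence_regressions(grids)
        assert (fits["be"] > fits["rce"]).all()

    def test_noise_ceiling_requires_replicates(self):
        grids = self.make_grids(lambda m1, m2, rce: rce, n_nets=1)
        fits = P.confidence_regressions(grids)
        assert "noise_ceiling" not in fits.columns
        assert fits.attrs.get("noise_ceiling_unavailable")


class TestEvidenceGridOnNetworks:
    def test_diagonal_accuracy_near_chance_and_swap_symmetry(self, two_choice_cohort, synth_pool):
        from confidence_lab.experiments import make_eval_grid_cell

        imgs, labels = synth_pool
        cell_eval = make_eval_grid_cell(imgs, labels, n_trials=120)
        net = two_choice_cohort[0]
        rng = np.random.default_rng(3)
        on_diag = cell_eval(net, mu_s1=0.6, mu_s2=0.6, sigma=1.5, rng=rng)
        # the diagonal has no correct answer: the decision split is wide but
        # cannot be extreme for a contrast-driven readout
        frac_s2 = (on_diag.df["decision"] == 1).mean()
        assert 0.02 < frac_s2 < 0.98
        a = cell_eval(net, mu_s1=0.3, mu_s2=0.9, sigma=1.5, rng=rng)
        b = cell_eval(net, mu_s1=0.9, mu_s2=0.3, sigma=1.5, rng=rng)
        assert abs(a.accuracy - b.accuracy) < 0.25  # symmetric up to sampling noise
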