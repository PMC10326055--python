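"""VAE and latent ideal observer: Bayes posterior, geometry, evaluation."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from confidence_lab import latent_model as L
from confidence_lab.synthetic_data import (
    LatentEvidenceSpec,
    make_synthetic_classes,
    reference_latent_spec,
    sample_latent_evidence,
)


def make_cg(sep=2.0, cov1=None, cov2=None):
    cov1 = np.eye(2) if cov1 is None else cov1
    cov2 = np.eye(2) if cov2 is None else cov2
    return L.ClassGaussians(np.array([-sep / 2, 0.0]), np.array([sep / 2, 0.0]), cov1, cov2)


class TestVAE:
    def test_kl_zero_at_prior(self):
        mean = np.zeros((5, 2))
        logvar = np.zeros((5, 2))
        assert L.kl_unit_normal(mean, logvar) == pytest.approx(0.0)

    def test_latent_dimensionality_is_two(self):
        vae = L.VAE(seed=0)
        assert vae.latent_dim == 2
        x = np.random.default_rng(0).uniform(-1, 1, (4, 32, 32))
        mean, logvar = vae.encode(x)
        assert mean.shape == (4, 2) and logvar.shape == (4, 2)

    def test_reconstruction_beats_mean_image_baseline(self):
        # images drawn from a 2-parameter family (class identity x contrast):
        # the 2-D latent suffices, so held-out denoising reconstruction must
        # beat predicting the mean clean image
        from confidence_lab.stimuli import apply_contrast_noise, contrast_scale

        protos, _ = make_synthetic_classes(1, separation=3.0, seed=10)
        imgs = np.tile(protos, (150, 1, 1))
        vae = L.VAE(seed=10)
        L.train_vae(vae, imgs, epochs=25, seed=10)
        rng = np.random.default_rng(11)
        idx = rng.integers(0, 2, 200)
        mu = rng.uniform(0.3, 1.0, size=200)
        clean = np.clip(contrast_scale(protos[idx], mu), -1, 1)
        noisy = apply_contrast_noise(protos[idx], mu, 1.0, rng)
        recon = vae.decode(vae.encode(noisy)[0])
        mse = float(((recon - clean) ** 2).mean())
        baseline = float(((clean - clean.mean(axis=0)) ** 2).mean())
        assert mse < baseline


class TestClassGaussians:
    def test_estimator_consistency(self):
        spec = reference_latent_spec()
        z, labels = sample_latent_evidence(spec, 10_000, seed=0)
        cg = L.ClassGaussians.from_samples(z, labels)
        n1 = (labels == 0).sum()
        se = np.sqrt(np.diag(spec.covariance("s1")) / n1)
        assert np.all(np.abs(cg.mean_s1 - spec.mean("s1")) < 3 * se)

    def test_duplicated_dataset_identical_fit(self):
        z, labels = sample_latent_evidence(LatentEvidenceSpec(mean_s2=(1, 1)), 500, seed=1)
        a = L.ClassGaussians.from_samples(z, labels)
        zz, ll = np.vstack([z, z]), np.concatenate([labels, labels])
        b = L.ClassGaussians.from_samples(zz, ll)
        assert np.allclose(a.mean_s1, b.mean_s1)
        # duplication only rescales the unbiased-covariance factor slightly
        assert np.allclose(a.cov_s1, b.cov_s1, rtol=5e-3)

    def test_covariance_symmetric(self):
        z, labels = sample_latent_evidence(reference_latent_spec(), 300, seed=2)
        cg = L.ClassGaussians.from_samples(z, labels)
        assert np.array_equal(cg.cov_s1, cg.cov_s1.T)

    def test_too_few_samples_rejected(self):
        z = np.zeros((4, 2))
        labels = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError, match="fewer than 3"):
            L.ClassGaussians.from_samples(z, labels)

    def test_serialization_roundtrip(self, tmp_path):
        z, labels = sample_latent_evidence(reference_latent_spec(), 300, seed=3)
        cg = L.ClassGaussians.from_samples(z, labels)
        cg.save(tmp_path / "cg.json")
        back = L.ClassGaussians.load(tmp_path / "cg.json")
        assert np.allclose(back.cov_s2, cg.cov_s2)


class TestGeometry:
    def test_isotropic_flagged_degenerate(self):
        cg = make_cg()
        with pytest.warns(L.DegenerateGeometryWarning):
            geom = L.latent_geometry(cg)
        assert geom.ratio == pytest.approx(1.0)
        assert geom.angle == 0.0 and geom.degenerate

    def test_constructed_axes_angle(self):
        spec = LatentEvidenceSpec(
            sd_major=2.0, sd_minor=1.0, axis_angle_s1=30.0, axis_angle_s2=81.4
        )
        cg = make_cg(cov1=spec.covariance("s1"), cov2=spec.covariance("s2"))
        geom = L.latent_geometry(cg)
        assert geom.angle == pytest.approx(51.4, abs=1e-6)
        assert geom.ratio == pytest.approx(2.0, abs=1e-9)

    def test_joint_rotation_invariance(self):
        spec = LatentEvidenceSpec(sd_major=1.7, sd_minor=0.6, axis_angle_s1=10.0, axis_angle_s2=60.0)
        cg = make_cg(cov1=spec.covariance("s1"), cov2=spec.covariance("s2"))
        base = L.latent_geometry(cg)
        rng = np.random.default_rng(4)
        for _ in range(5):
            th = rng.uniform(0, np.pi)
            r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            rot = L.ClassGaussians(
                r @ cg.mean_s1, r @ cg.mean_s2, r @ cg.cov_s1 @ r.T, r @ cg.cov_s2 @ r.T
            )
            geom = L.latent_geometry(rot)
            assert geom.ratio == pytest.approx(base.ratio, abs=1e-9)
            assert geom.angle == pytest.approx(base.angle, abs=1e-6)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError):
            L.ClassGaussians(np.zeros(2), np.ones(2), -np.eye(2), np.eye(2))


class TestIdealObserver:
    def test_posteriors_sum_to_one(self):
        cg = make_cg(sep=1.5, cov2=2 * np.eye(2))
        z = np.random.default_rng(5).normal(size=(50, 2))
        p1, p2 = L.io_posterior(cg, z)
        assert np.allclose(p1 + p2, 1.0)

    def test_symmetry_axis_gives_half(self):
        cg = make_cg(sep=2.0)
        z = np.column_stack([np.zeros(9), np.linspace(-3, 3, 9)])
        p1, _ = L.io_posterior(cg, z)
        assert np.allclose(p1, 0.5, atol=1e-12)

    def test_agrees_with_direct_density_oracle(self):
        # independent oracle: scipy multivariate normal densities + Bayes
        rng = np.random.default_rng(6)
        for _ in range(100):
            m1, m2 = rng.normal(size=(2, 2))
            a = rng.normal(size=(2, 2))
            b = rng.normal(size=(2, 2))
            cov1 = a @ a.T + 0.3 * np.eye(2)
            cov2 = b @ b.T + 0.3 * np.eye(2)
            cg = L.ClassGaussians(m1, m2, cov1, cov2)
            z = rng.normal(scale=2.0, size=(1, 2))
            f1 = multivariate_normal(m1, cov1).pdf(z[0])
            f2 = multivariate_normal(m2, cov2).pdf(z[0])
            expected = f1 * 0.5 / (f1 * 0.5 + f2 * 0.5)
            p1, _ = L.io_posterior(cg, z)
            assert abs(p1[0] - expected) < 1e-6

    def test_confidence_at_least_half_and_certain_at_mean(self):
        cg = make_cg(sep=8.0)
        z = np.random.default_rng(7).normal(scale=3.0, size=(200, 2))
        dec, conf = L.io_decide_confidence(cg, z)
        assert np.all(conf >= 0.5)
        d0, c0 = L.io_decide_confidence(cg, np.array([cg.mean_s1]))
        assert d0[0] == 0 and c0[0] > 0.99

    def test_exact_tie_breaks_to_s1(self):
        cg = make_cg(sep=2.0)
        dec, conf = L.io_decide_confidence(cg, np.array([[0.0, 0.0]]))
        assert dec[0] == 0 and conf[0] == pytest.approx(0.5)

    def test_posterior_monotone_along_mean_axis(self):
        cg = make_cg(sep=3.0)  # shared covariance
        t = np.linspace(0, 1, 50)
        z = (1 - t)[:, None] * cg.mean_s2 + t[:, None] * cg.mean_s1
        p1, _ = L.io_posterior(cg, z)
        assert np.all(np.diff(p1) > 0)

    def test_self_consistency_and_mc_stability(self):
        cg = make_cg(sep=2.0)
        acc1, conf1 = L.io_evaluate_condition(cg, cg, n_mc=100_000, seed=1)
        acc2, conf2 = L.io_evaluate_condition(cg, cg, n_mc=100_000, seed=2)
        assert abs(acc1 - acc2) < 0.01 and abs(conf1 - conf2) < 0.01
        # confidence upper-bounds accuracy when test matches training
        assert conf1 >= acc1 - 0.01

    def test_small_mc_count_warns(self):
        cg = make_cg()
        with pytest.warns(UserWarning, match="n_mc"):
            L.io_evaluate_condition(cg, cg, n_mc=50, seed=0)

    def test_pe_bias_direction_under_reference_geometry(self):
        # matched-accuracy low/high PE latent conditions: higher confidence
        # in the high-PE (larger signal, larger noise) condition
        from confidence_lab.psychophysics import calibrate_contrast

        spec = reference_latent_spec()
        z, lab = sample_latent_evidence(spec, 20_000, seed=8)
        cg_train = L.ClassGaussians.from_samples(z, lab)

        def condition(scale, noise_sd):
            c1 = spec.covariance("s1") * scale**2 + noise_sd**2 * np.eye(2)
            c2 = spec.covariance("s2") * scale**2 + noise_sd**2 * np.eye(2)
            return L.ClassGaussians(
                np.asarray(spec.mean_s1) * scale, np.asarray(spec.mean_s2) * scale, c1, c2
            )

        grid = np.linspace(0.2, 3.0, 15)
        results = {}
        for name, noise_sd in (("low", 0.3), ("high", 1.0)):
            cal = calibrate_contrast(
                lambda s, nsd=noise_sd: L.io_evaluate_condition(cg_train, condition(s, nsd), 40_000, seed=9)[0],
                0.75,
                grid,
            )
            results[name] = L.io_evaluate_condition(
                cg_train, condition(cal.fitted_value, noise_sd), 40_000, seed=10
            )
        acc_low, conf_low = results["low"]
        acc_high, conf_high = results["high"]
        assert abs(acc_low - acc_high) < 0.02  # balance gate
        assert conf_high > conf_low
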