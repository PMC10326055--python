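"""Confidence networks: architecture contracts, training, evaluation."""

import numpy as np
import pytest

from confidence_lab import networks as N
from confidence_lab.stimuli import apply_contrast_noise
from confidence_lab.synthetic_data import make_synthetic_classes


@pytest.fixture(scope="module")
def small_batch(rng=None):
    gen = np.random.default_rng(5)
    return gen.uniform(-1, 1, size=(8, 32, 32))


class TestArchitecture:
    def test_encoder_output_is_100_dimensional(self, small_batch):
        net = N.build_confidence_network("two_choice", seed=0)
        feat = net.encoder.forward(small_batch)
        assert feat.shape == (8, 100)

    def test_ten_choice_probabilities_normalized(self, small_batch):
        net = N.build_confidence_network("ten_choice", seed=0)
        probs, conf = net.forward(small_batch)
        assert probs.shape == (8, 10)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((conf >= 0) & (conf <= 1))

    def test_two_choice_emits_single_probability(self, small_batch):
        net = N.build_confidence_network("two_choice", seed=0)
        probs, conf = net.forward(small_batch)
        assert probs.shape == (8,)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_actor_critic_action_probabilities(self, small_batch):
        net = N.build_confidence_network("rl_gabor", seed=0)
        probs, v = net.forward(small_batch)
        assert probs.shape == (8, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert v.shape == (8,)

    def test_all_layer_activations_concat_to_11236(self, small_batch):
        # 8192 + 2048 + 512 + 256 + 128 + 100
        net = N.build_confidence_network("two_choice", seed=0)
        _, _, acts = net.forward(small_batch, record=True)
        total = sum(a.shape[1] for a in acts.values())
        assert total == 11236

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            N.build_confidence_network("three_choice")


@pytest.fixture(scope="module")
def trained():
    imgs, labels = make_synthetic_classes(400, separation=5.0, seed=21)
    net = N.build_confidence_network("two_choice", seed=21)
    log = N.train_supervised(net, imgs, labels, regime="standard", epochs=3, seed=21)
    return net, log


class TestSupervisedTraining:

    def test_loss_decreases(self, trained):
        _, log = trained
        assert log["loss"].iloc[-1] < log["loss"].iloc[0]

    def test_high_separation_reaches_high_heldout_accuracy(self, trained):
        net, _ = trained
        imgs, labels = make_synthetic_classes(300, separation=5.0, seed=77)
        x = apply_contrast_noise(imgs, 0.8, 0.5, seed=3)
        rec = N.evaluate_trials(net, x, labels)
        assert rec.accuracy > 0.95

    def test_confidence_higher_on_correct_trials(self, trained):
        net, _ = trained
        imgs, labels = make_synthetic_classes(400, separation=5.0, seed=78)
        x = apply_contrast_noise(imgs, 0.35, 1.5, seed=4)  # hard enough for errors
        rec = N.evaluate_trials(net, x, labels)
        df = rec.df
        assert 0.05 < df["correct"].mean() < 1.0
        assert df.loc[df["correct"], "confidence"].mean() > df.loc[~df["correct"], "confidence"].mean()

    def test_empty_data_rejected(self):
        net = N.build_confidence_network("two_choice", seed=0)
        with pytest.raises(ValueError):
            N.train_supervised(net, np.empty((0, 32, 32)), np.empty(0))

    def test_training_reproducible_from_seed(self):
        imgs, labels = make_synthetic_classes(40, separation=3.0, seed=1)
        nets = []
        for _ in range(2):
            net = N.build_confidence_network("two_choice", seed=9)
            N.train_supervised(net, imgs, labels, epochs=1, seed=9)
            nets.append(net)
        for pa, pb in zip(nets[0].params(), nets[1].params()):
            assert np.array_equal(pa.value, pb.value)


class TestRLTraining:
    def test_opt_out_reward_update_rule(self):
        # previous-batch accuracy 0.9 caps the guaranteed reward at 0.75
        assert min(0.9, 0.75) == 0.75
        net = N.build_confidence_network("rl_gabor", seed=2)
        N.train_rl_actor_critic(net, N.gabor_batch_factory(), iterations=30, seed=2)
        assert 0.0 <= net.r_opt_out <= 0.75

    def test_zero_prediction_error_contributes_zero_actor_loss(self):
        # delta = r - v = 0 makes the actor-loss gradient vanish
        probs = np.array([[0.2, 0.3, 0.5]])
        actions = np.array([1])
        delta = np.array([0.0])
        dact = probs.copy()
        dact[np.arange(1), actions] -= 1.0
        dact *= delta[:, None]
        assert np.all(dact == 0.0)

    def test_opt_out_rate_decreases_with_contrast(self, rl_cohort):
        from confidence_lab.experiments import make_eval_gabor

        evaluate = make_eval_gabor(n_trials=300)
        rates = []
        for mu in (0.1, 0.3, 0.5, 0.7, 0.9):
            per_net = [
                evaluate(net, mu=mu, sigma=0.75, rng=np.random.default_rng((17, k, int(mu * 10))))
                .df["opt_out"]
                .mean()
                for k, net in enumerate(rl_cohort)
            ]
            rates.append(np.mean(per_net))
        # non-increasing trend over the contrast sweep (allow tiny noise)
        assert rates[-1] < rates[0]
        assert all(b <= a + 0.05 for a, b in zip(rates, rates[1:]))


class TestEvaluation:
    def test_record_length_and_correct_flags(self, small_batch):
        net = N.build_confidence_network("two_choice", seed=0)
        labels = np.array([0, 1] * 4)
        rec = N.evaluate_trials(net, small_batch, labels)
        assert len(rec) == 8
        assert np.array_equal(
            rec.df["correct"].to_numpy(), rec.df["decision"].to_numpy() == labels
        )

    def test_rl_forced_choice_decisions_cover_all_trials(self, rl_cohort):
        gen = np.random.default_rng(6)
        x = gen.uniform(-1, 1, size=(50, 32, 32))
        rec = N.evaluate_trials(rl_cohort[0], x, gen.integers(0, 2, 50))
        assert set(rec.df["decision"].unique()) <= {0, 1}
        assert np.isfinite(rec.accuracy)
        # chosen_accuracy drops opt-out trials from the denominator
        if rec.df["opt_out"].any():
            held = ~rec.df["opt_out"]
            assert rec.chosen_accuracy == pytest.approx(rec.df.loc[held, "correct"].mean())

    def test_checkpoint_roundtrip_preserves_outputs(self, tmp_path, small_batch):
        net = N.build_confidence_network("two_choice", seed=13)
        p0, c0 = net.forward(small_batch)
        path = tmp_path / "net.npz"
        N.save_checkpoint(net, path)
        restored = N.load_checkpoint(path)
        p1, c1 = restored.forward(small_batch)
        assert np.array_equal(p0, p1) and np.array_equal(c0, c1)
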