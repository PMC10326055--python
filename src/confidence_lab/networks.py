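"""Performance-optimized confidence networks and the RL actor-critic.

The shared encoder maps a 32x32 grayscale stimulus to a 100-dimensional
feature vector: three stride-2 3x3 convolutions (32 channels each, batch
normalization, leaky-ReLU slope 0.01) followed by fully connected layers of
256 and 128 units (batch norm + leaky ReLU) and a linear 100-unit output.

Supervised variant: a classification head (softmax over 10 classes, or a
single sigmoid unit read as p(class = s2) for two-choice tasks) and a
confidence head (single sigmoid unit) trained to predict the probability
that the classification response is correct. The two cross-entropy losses
are summed and the whole architecture is trained jointly with Adam.

RL variant (opt-out task): an actor head over {LEFT, RIGHT, OPT-OUT} and a
linear critic predicting trial reward. Correct choices earn reward 1,
errors 0; opting out earns a guaranteed r_opt-out that tracks recent
accuracy, r_opt-out = min(p(correct on previous batch), 0.75), starting at
0.5 so the network cannot lock into always opting out early in training.
The critic is trained with a smooth-L1 (Huber) loss; the actor loss is
-log p(a_t) * delta_t with reward-prediction error delta_t = r_t - v_t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .stimuli import Regime, apply_contrast_noise, sample_regime

ENCODER_BLOCKS = ("conv1", "conv2", "conv3", "fc1", "fc2", "encoder_out")
LEFT, RIGHT, OPT_OUT = 0, 1, 2


class Encoder:
    """The shared convolutional encoder, organised as named blocks so that
    activations can be recorded or perturbed at any stage."""

    def __init__(self, rng: np.random.Generator):
        self.blocks = [
            nn.Sequential(nn.Conv2d(1, 32, 3, 2, 1, rng), nn.BatchNorm(32), nn.LeakyReLU(0.01)),
            nn.Sequential(nn.Conv2d(32, 32, 3, 2, 1, rng), nn.BatchNorm(32), nn.LeakyReLU(0.01)),
            nn.Sequential(nn.Conv2d(32, 32, 3, 2, 1, rng), nn.BatchNorm(32), nn.LeakyReLU(0.01)),
            nn.Sequential(nn.Flatten(), nn.Linear(512, 256, rng), nn.BatchNorm(256), nn.LeakyReLU(0.01)),
            nn.Sequential(nn.Linear(256, 128, rng), nn.BatchNorm(128), nn.LeakyReLU(0.01)),
            nn.Sequential(nn.Linear(128, 100, rng)),
        ]

    def params(self):
        return [p for b in self.blocks for p in b.params()]

    def forward(self, x, train=False, record=False, perturb=None):
        """Run the encoder. ``perturb`` is an optional callable
        ``(block_index, activations) -> activations`` applied after each
        block's nonlinearity. With ``record=True`` also returns a dict of
        per-block activations (flattened to 2-D)."""
        acts = {} if record else None
        if x.ndim == 3:
            x = x[:, None]
        for i, block in enumerate(self.blocks):
            x = block.forward(x, train=train)
            if perturb is not None:
                x = perturb(i, x)
            if record:
                acts[ENCODER_BLOCKS[i]] = x.reshape(x.shape[0], -1).copy()
        return (x, acts) if record else x

    def backward(self, dfeat):
        for block in reversed(self.blocks):
            dfeat = block.backward(dfeat)
        return dfeat


@dataclass
class BehavioralRecord:
    """Tidy per-trial record of an evaluation run.

    ``df`` columns: trial, mu (or mu_s1/mu_s2), sigma, label, decision,
    confidence, opt_out, correct. Correctness is undefined (NaN-free but
    masked) on opt-out trials. ``activations`` optionally maps encoder block
    names to (n_trials, n_units) arrays.
    """

    df: pd.DataFrame
    activations: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.df)

    @property
    def accuracy(self) -> float:
        """Decision accuracy over all trials. For the RL task the decision
        is the forced choice read from the argmax over LEFT/RIGHT, ignoring
        the OPT-OUT output, so every trial contributes."""
        return float(self.df["correct"].mean())

    @property
    def chosen_accuracy(self) -> float:
        """Accuracy restricted to trials the network did not opt out of."""
        held = ~self.df["opt_out"].to_numpy()
        if held.sum() == 0:
            return np.nan
        return float(self.df.loc[held, "correct"].mean())

    def save(self, path):
        self.df.to_csv(path, index=False)

    @classmethod
    def concat(cls, records: list["BehavioralRecord"]) -> "BehavioralRecord":
        df = pd.concat([r.df for r in records], ignore_index=True)
        df["trial"] = np.arange(len(df))
        acts = {}
        if records and records[0].activations:
            for k in records[0].activations:
                acts[k] = np.concatenate([r.activations[k] for r in records])
        return cls(df, acts)


class ConfidenceNetwork:
    def __init__(self, task: str, seed: int = 0):
        if task not in ("two_choice", "ten_choice"):
            raise ValueError(f"unknown task {task!r}")
        self.task = task
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(rng)
        n_out = 1 if task == "two_choice" else 10
        self.class_head = nn.Linear(100, n_out, rng)
        self.conf_head = nn.Linear(100, 1, rng)

    def params(self):
        return self.encoder.params() + self.class_head.params() + self.conf_head.params()

    def forward(self, images, train=False, record=False, perturb=None):
        """Return (class_prob, confidence[, activations]).

        ``class_prob`` is (n,) p(s2) for two-choice or (n, 10) softmax rows
        for ten-choice; ``confidence`` is (n,) in [0, 1].
        """
        out = self.encoder.forward(images, train=train, record=record, perturb=perturb)
        feat, acts = out if record else (out, None)
        class_logit = self.class_head.forward(feat, train=train)
        conf_logit = self.conf_head.forward(feat, train=train)
        if self.task == "two_choice":
            class_prob = nn.sigmoid(class_logit[:, 0])
        else:
            class_prob = nn.softmax(class_logit, axis=1)
        conf = nn.sigmoid(conf_logit[:, 0])
        return (class_prob, conf, acts) if record else (class_prob, conf)

    def decisions(self, class_prob):
        if self.task == "two_choice":
            return (class_prob >= 0.5).astype(int)
        return class_prob.argmax(axis=1)


class ActorCritic:
    def __init__(self, seed: int = 0):
        self.task = "rl_gabor"
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(rng)
        self.actor = nn.Linear(100, 3, rng)
        self.critic = nn.Linear(100, 1, rng)
        self.r_opt_out = 0.5

    def params(self):
        return self.encoder.params() + self.actor.params() + self.critic.params()

    def forward(self, images, train=False, record=False, perturb=None):
        """Return (action_probs (n,3), value (n,)[, activations])."""
        out = self.encoder.forward(images, train=train, record=record, perturb=perturb)
        feat, acts = out if record else (out, None)
        probs = nn.softmax(self.actor.forward(feat, train=train), axis=1)
        v = self.critic.forward(feat, train=train)[:, 0]
        return (probs, v, acts) if record else (probs, v)


def build_confidence_network(task: str, seed: int = 0):
    """Factory for the three task variants."""
    if task == "rl_gabor":
        return ActorCritic(seed=seed)
    return ConfidenceNetwork(task, seed=seed)


# ---------------------------------------------------------------------------
# Supervised training


def train_supervised(
    net: ConfidenceNetwork,
    raw_images: np.ndarray,
    labels: np.ndarray,
    regime: Regime | str = "standard",
    epochs: int = 5,
    lr: float = 5e-4,
    batch_size: int = 32,
    seed: int = 0,
) -> pd.DataFrame:
    """Train class + confidence heads jointly on raw [0,1] images whose
    contrast/noise are sampled online from the regime. The confidence target
    is recomputed each step from the current classification output (1 if the
    decision would be correct, else 0). Returns a per-epoch training log."""
    if len(raw_images) == 0:
        raise ValueError("empty training set")
    labels = np.asarray(labels)
    if net.task == "two_choice":
        classes = np.unique(labels)
        if len(classes) != 2:
            raise ValueError("two_choice task requires exactly 2 classes")
        y_all = (labels == classes[1]).astype(int)
    else:
        y_all = labels.astype(int)
    rng = np.random.default_rng(seed)
    opt = nn.Adam(net.params(), lr=lr)
    log = []
    n = len(raw_images)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, accs = [], []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if len(idx) < 2:
                continue  # batch norm needs more than one sample
            musig = sample_regime(regime, len(idx), rng)
            x = apply_contrast_noise(raw_images[idx], musig[:, 0], musig[:, 1], rng)
            y = y_all[idx]
            opt.zero_grad()
            class_prob, conf = net.forward(x, train=True)
            m = len(idx)
            if net.task == "two_choice":
                decision = (class_prob >= 0.5).astype(int)
                loss_class = -np.mean(y * np.log(class_prob + 1e-12) + (1 - y) * np.log(1 - class_prob + 1e-12))
                dclass_logit = ((class_prob - y) / m)[:, None]
            else:
                decision = class_prob.argmax(axis=1)
                loss_class = -np.mean(np.log(class_prob[np.arange(m), y] + 1e-12))
                dclass_logit = class_prob.copy()
                dclass_logit[np.arange(m), y] -= 1.0
                dclass_logit /= m
            correct = (decision == y).astype(float)
            loss_conf = -np.mean(correct * np.log(conf + 1e-12) + (1 - correct) * np.log(1 - conf + 1e-12))
            dconf_logit = ((conf - correct) / m)[:, None]
            dfeat = net.class_head.backward(dclass_logit) + net.conf_head.backward(dconf_logit)
            net.encoder.backward(dfeat)
            opt.step()
            losses.append(loss_class + loss_conf)
            accs.append(correct.mean())
        log.append({"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": float(np.mean(accs))})
    return pd.DataFrame(log)


# ---------------------------------------------------------------------------
# RL training on the orientation-discrimination opt-out task


def train_rl_actor_critic(
    net: ActorCritic,
    make_batch,
    iterations: int = 5000,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
    log_every: int = 100,
) -> pd.DataFrame:
    """Train the actor-critic with sampled actions and batch-level updates of
    the guaranteed opt-out reward.

    ``make_batch(batch_size, rng) -> (images, labels)`` supplies processed
    stimuli with labels in {0 (LEFT), 1 (RIGHT)}; see
    :func:`gabor_batch_factory`.
    """
    rng = np.random.default_rng(seed)
    opt = nn.Adam(net.params(), lr=lr)
    log = []
    for it in range(iterations):
        x, y = make_batch(batch_size, rng)
        m = len(x)
        opt.zero_grad()
        probs, v = net.forward(x, train=True)
        u = rng.random(m)
        actions = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(0, 2)
        chose = actions != OPT_OUT
        reward = np.where(chose, (actions == y).astype(float), net.r_opt_out)
        delta = reward - v
        # critic: smooth-L1 loss gradient (Huber, delta=1)
        dv = np.clip(v - reward, -1.0, 1.0) / m
        # actor: d/dlogits of -log p(a_t) * delta (delta treated as constant)
        dact = probs.copy()
        dact[np.arange(m), actions] -= 1.0
        dact *= delta[:, None] / m
        dfeat = net.actor.backward(dact) + net.critic.backward(dv[:, None])
        net.encoder.backward(dfeat)
        opt.step()
        if chose.any():
            net.r_opt_out = min(float((actions[chose] == y[chose]).mean()), 0.75)
        if it % log_every == 0 or it == iterations - 1:
            log.append(
                {
                    "iteration": it,
                    "accuracy": float((actions[chose] == y[chose]).mean()) if chose.any() else np.nan,
                    "opt_out_rate": float((~chose).mean()),
                    "mean_reward": float(reward.mean()),
                    "r_opt_out": net.r_opt_out,
                }
            )
    return pd.DataFrame(log)


def gabor_batch_factory(regime: Regime | str = "gabor", sigma_is_variance: bool = False):
    """Return a make_batch callable producing tilted-Gabor trials with
    regime-sampled contrast and noise. Label 0 = -5 deg (LEFT), 1 = +5 deg
    (RIGHT)."""
    from .stimuli import GaborSpec, gabor_patch

    raw = {0: gabor_patch(GaborSpec(tilt=-5.0)), 1: gabor_patch(GaborSpec(tilt=5.0))}

    def make_batch(batch_size, rng):
        y = rng.integers(0, 2, size=batch_size)
        imgs = np.stack([raw[lab] for lab in y])
        musig = sample_regime(regime, batch_size, rng)
        x = apply_contrast_noise(imgs, musig[:, 0], musig[:, 1], rng, sigma_is_variance)
        return x, y

    return make_batch


# ---------------------------------------------------------------------------
# Evaluation


def evaluate_trials(
    net,
    images: np.ndarray,
    labels: np.ndarray,
    meta: pd.DataFrame | None = None,
    store_activations: bool = False,
    perturb=None,
    batch_size: int = 256,
) -> BehavioralRecord:
    """Evaluate a trained network on processed stimuli (eval-mode batch
    norm, argmax decisions). For the RL variant, a trial is an opt-out when
    OPT-OUT is the argmax over all three actions, decisions are the argmax
    over LEFT/RIGHT only, and the recorded ``confidence`` is 1 - p(OPT-OUT)
    (the implicit confidence readout)."""
    labels = np.asarray(labels)
    rows = []
    acts_parts = []
    for start in range(0, len(images), batch_size):
        x = images[start : start + batch_size]
        y = labels[start : start + batch_size]
        if isinstance(net, ActorCritic):
            out = net.forward(x, train=False, record=store_activations, perturb=perturb)
            probs, _v = out[0], out[1]
            acts = out[2] if store_activations else None
            opt_out = probs.argmax(axis=1) == OPT_OUT
            decision = probs[:, :2].argmax(axis=1)
            confidence = 1.0 - probs[:, OPT_OUT]
            extra = {"p_left": probs[:, 0], "p_right": probs[:, 1], "p_opt_out": probs[:, 2]}
        else:
            out = net.forward(x, train=False, record=store_activations, perturb=perturb)
            class_prob, confidence = out[0], out[1]
            acts = out[2] if store_activations else None
            decision = net.decisions(class_prob)
            opt_out = np.zeros(len(x), dtype=bool)
            extra = {"class_prob": class_prob if class_prob.ndim == 1 else class_prob.max(axis=1)}
        rows.append(
            pd.DataFrame(
                {
                    "label": y,
                    "decision": decision,
                    "confidence": confidence,
                    "opt_out": opt_out,
                    "correct": (decision == y),
                    **extra,
                }
            )
        )
        if store_activations:
            acts_parts.append(acts)
    df = pd.concat(rows, ignore_index=True)
    df.insert(0, "trial", np.arange(len(df)))
    if meta is not None:
        for col in meta.columns:
            if col not in df.columns:
                df[col] = np.asarray(meta[col])
    activations = {}
    if store_activations:
        for k in ENCODER_BLOCKS:
            activations[k] = np.concatenate([a[k] for a in acts_parts])
    return BehavioralRecord(df, activations)


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(net, path):
    """Single-file archive of parameters + architecture tag + seed."""
    arrays = {}
    idx = 0
    for p in net.params():
        arrays[f"p{idx}"] = p.value
        idx += 1
    bn_idx = 0
    for block in net.encoder.blocks:
        for layer in block.layers:
            if isinstance(layer, nn.BatchNorm):
                arrays[f"bn{bn_idx}_mean"] = layer.running_mean
                arrays[f"bn{bn_idx}_var"] = layer.running_var
                bn_idx += 1
    extra = {}
    if isinstance(net, ActorCritic):
        extra["r_opt_out"] = net.r_opt_out
    np.savez(path, task=net.task, seed=net.seed, **arrays, **{f"x_{k}": v for k, v in extra.items()})


def load_checkpoint(path):
    data = np.load(path, allow_pickle=False)
    task = str(data["task"])
    seed = int(data["seed"])
    net = build_confidence_network(task, seed=seed)
    for idx, p in enumerate(net.params()):
        p.value[...] = data[f"p{idx}"]
    bn_idx = 0
    for block in net.encoder.blocks:
        for layer in block.layers:
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = data[f"bn{bn_idx}_mean"]
                layer.running_var[...] = data[f"bn{bn_idx}_var"]
                bn_idx += 1
    if isinstance(net, ActorCritic) and "x_r_opt_out" in data:
        net.r_opt_out = float(data["x_r_opt_out"])
    return net
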