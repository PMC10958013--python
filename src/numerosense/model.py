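"""Siamese perception network trained on action prediction.

The perception module maps a rendered scene image to a low-dimensional
embedding z through a convolutional front-end whose first three layers are
frozen (a seeded random feature bank — random convolutional networks are
already known to carry coarse quantity-sensitive features), four trainable
convolutional layers, and two fully connected layers.  A two-layer
classifier head compares the embeddings of the before/after images of a
manipulation — the same perception network applied to both, so parameters
are shared by construction — and predicts which of PUT / TAKE / SHAKE took
place.  Training minimizes the NLL of the true action; no count label is
ever shown to the network.

Two layer-plan profiles are provided: ``full`` for 244 px images matching
the simulation's native resolution, and ``desk`` for 96 px images with
narrower layers, sized so a complete study runs in minutes on one CPU core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from . import scenes
from ._nn import Adam, Conv2d, Flatten, Linear, ReLU, Sequential, log_softmax, nll_loss_grad

ACTION_INDEX = {scenes.ActionKind.PUT: 0, scenes.ActionKind.TAKE: 1, scenes.ActionKind.SHAKE: 2}
ACTION_ORDER = ("P", "T", "S")

# (c_out, kernel, stride) per conv layer; 3 frozen + 4 trainable, then 2 FC.
_PROFILES = {
    # kernel/stride chains tile the image exactly ((in - k) % stride == 0 at
    # every layer), so the embedding's receptive field covers every pixel —
    # an object near the border is as visible as one in the center.
    "desk": dict(input_size=64,
                 frozen=[(16, 6, 2), (32, 4, 2), (32, 3, 1)],
                 trainable=[(32, 3, 1), (64, 4, 2), (64, 3, 1), (64, 2, 1)],
                 fc_hidden=128, clf_hidden=64),
    "full": dict(input_size=244,
                 frozen=[(16, 11, 5), (32, 5, 2), (32, 3, 1)],
                 trainable=[(32, 3, 1), (64, 3, 2), (64, 3, 1), (64, 3, 1)],
                 fc_hidden=128, clf_hidden=64),
}


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters of the perception + classifier pair."""

    embedding_dim: int = 2
    profile: str = "desk"
    frozen_frontend: str = "seeded-random-conv"

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.embedding_dim > 256:
            raise ValueError("embedding_dim above 256 is unsupported")
        if self.profile not in _PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.frozen_frontend != "seeded-random-conv":
            raise ValueError(
                "only the seeded-random-conv front-end is available; pretrained "
                "early-conv features would require external weights")

    @property
    def input_size(self) -> int:
        return _PROFILES[self.profile]["input_size"]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization schedule.  The product epochs x minibatches x actions is
    the exact number of labeled image pairs consumed (each mini-batch is one
    fresh play episode of ``actions_per_minibatch`` manipulations)."""

    learning_rate: float = 1e-4
    epochs: int = 30
    minibatches_per_epoch: int = 30
    actions_per_minibatch: int = 180
    cooldown_epochs: int = 0      # final epochs at learning_rate / 10
    seed: int | None = None

    @property
    def total_pairs(self) -> int:
        return self.epochs * self.minibatches_per_epoch * self.actions_per_minibatch


def desk_schedule(**kw) -> TrainingConfig:
    """Schedule paired with the desk profile: a higher base rate than the
    full profile (the desk network is far smaller) plus a final cooldown
    phase at a tenth of the rate, which tightens the per-count embedding
    islands by shrinking late-training gradient jitter."""
    kw.setdefault("epochs", 120)
    kw.setdefault("learning_rate", 1e-3)
    kw.setdefault("cooldown_epochs", max(1, kw["epochs"] // 6))
    return TrainingConfig(**kw)


class PerceptionModel:
    """Shared-weight perception network plus the 3-way action classifier."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        plan = _PROFILES[config.profile]
        size, c_in = plan["input_size"], 1

        frozen_layers = []
        for c_out, k, s in plan["frozen"]:
            conv = Conv2d(c_in, c_out, k, s, rng, trainable=False)
            frozen_layers += [conv, ReLU()]
            size, c_in = conv.out_size(size), c_out
        self.frontend = Sequential(frozen_layers)

        trunk_layers = []
        for c_out, k, s in plan["trainable"]:
            conv = Conv2d(c_in, c_out, k, s, rng)
            trunk_layers += [conv, ReLU()]
            size, c_in = conv.out_size(size), c_out
        flat = c_in * size * size
        trunk_layers += [Flatten(),
                         Linear(flat, plan["fc_hidden"], rng), ReLU(),
                         Linear(plan["fc_hidden"], config.embedding_dim, rng)]
        self.trunk = Sequential(trunk_layers)

        d = config.embedding_dim
        self.classifier = Sequential([
            Linear(2 * d, plan["clf_hidden"], rng), ReLU(),
            Linear(plan["clf_hidden"], 3, rng)])
        self.calibrated = False

    def calibrate(self, images: np.ndarray) -> None:
        """Normalize activation scales on a batch of sample scene images.

        Scene images are sparse (a few bright squares on a black field), so
        fan-in initialization alone leaves activations far below unit scale;
        each weighted layer — including the frozen random front-end, whose
        output scale is part of its seeding — is rescaled once so that its
        pre-activation standard deviation on this batch is 1.
        """
        x = self._check_images(images)
        h = self.frontend.calibrate(x)
        z = self.trunk.calibrate(h)
        self.classifier.calibrate(np.concatenate([z[:-1], z[1:]], axis=1))
        self.calibrated = True

    # -- inference ---------------------------------------------------------

    def _check_images(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 2:
            images = images[None]
        n = self.config.input_size
        if images.shape[-2:] != (n, n):
            raise ValueError(f"expected {n}x{n} images, got {images.shape[-2:]}")
        return images[..., None]  # channels-last

    def embed(self, images: np.ndarray, batch_size: int = 256,
              cache: bool = False) -> np.ndarray:
        """Embed images, one row per image.  Deterministic at inference."""
        x = self._check_images(images)
        if cache:                       # training path: single batch
            return self.trunk.forward(self.frontend.forward(x, False), True)
        out = [self.trunk.forward(self.frontend.forward(x[i:i + batch_size], False), False)
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def predict_action(self, images_before: np.ndarray,
                       images_after: np.ndarray) -> np.ndarray:
        """Probabilities over (P, T, S) for each before/after pair."""
        zb = self.embed(images_before)
        za = self.embed(images_after)
        logits = self.classifier.forward(np.concatenate([zb, za], axis=1), False)
        return np.exp(log_softmax(logits))

    def frozen_checksum(self) -> float:
        """Invariant under training: sum of |w| over the frozen front-end."""
        total = 0.0
        for layer in self.frontend.layers:
            if isinstance(layer, Conv2d):
                total += float(np.abs(layer.W).sum() + np.abs(layer.b).sum())
        return total

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file .npz checkpoint with the config snapshot embedded."""
        arrays = {"__config__": np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)}
        for prefix, seq in (("f", self.frontend), ("t", self.trunk), ("c", self.classifier)):
            for i, layer in enumerate(seq.layers):
                if hasattr(layer, "W"):
                    arrays[f"{prefix}{i}_W"] = layer.W
                    arrays[f"{prefix}{i}_b"] = layer.b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PerceptionModel":
        data = np.load(path)
        config = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = cls(config, np.random.default_rng(0))
        for prefix, seq in (("f", model.frontend), ("t", model.trunk), ("c", model.classifier)):
            for i, layer in enumerate(seq.layers):
                if hasattr(layer, "W"):
                    layer.W = data[f"{prefix}{i}_W"].copy()
                    layer.b = data[f"{prefix}{i}_b"].copy()
        model.calibrated = True  # checkpoints hold post-calibration weights
        return model


def build_model(config: ModelConfig, rng: np.random.Generator) -> PerceptionModel:
    """Construct the Siamese model; the same weights serve both branches."""
    return PerceptionModel(config, rng)


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainingHistory:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_accuracy: list[float] = field(default_factory=list)
    pairs_consumed: int = 0

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"epoch": np.arange(1, len(self.epoch_loss) + 1),
                             "mean_loss": self.epoch_loss,
                             "train_accuracy": self.epoch_accuracy})


def _sequence_arrays(records: Sequence[scenes.ActionRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Distinct frames of an episode plus per-pair action indices."""
    frames = np.stack([records[0].image_before] + [r.image_after for r in records])
    labels = np.asarray([ACTION_INDEX[r.action] for r in records], dtype=np.int64)
    return frames, labels


def train(model: PerceptionModel,
          scene_stream: Iterator[Sequence[scenes.ActionRecord]],
          training_config: TrainingConfig,
          rng: np.random.Generator,
          shuffle_labels: bool = False) -> TrainingHistory:
    """Train perception and classifier jointly on action prediction.

    Each mini-batch is one fresh episode: its n+1 frames are embedded once,
    consecutive embeddings are paired as (z_t, z_{t+1}) and classified, and
    the embedding gradient accumulates contributions from both roles of
    every shared frame.  ``shuffle_labels`` permutes action labels within
    each mini-batch (a no-signal control that must stay at chance).
    """
    cfg = training_config
    if not model.calibrated:
        # activation-scale calibration on one dedicated episode (not counted
        # against the training schedule's pair budget)
        frames, _ = _sequence_arrays(next(scene_stream))
        model.calibrate(frames)
    opt = Adam([model.trunk, model.classifier], lr=cfg.learning_rate)
    history = TrainingHistory()
    for epoch in range(cfg.epochs):
        if epoch == cfg.epochs - cfg.cooldown_epochs:
            opt.lr = cfg.learning_rate / 10.0
        losses, hits, seen = [], 0, 0
        for _ in range(cfg.minibatches_per_epoch):
            records = next(scene_stream)
            if len(records) != cfg.actions_per_minibatch:
                raise ValueError("stream episode length does not match the schedule")
            frames, labels = _sequence_arrays(records)
            if shuffle_labels:
                labels = rng.permutation(labels)

            z = model.embed(frames, cache=True)              # (n+1, d)
            pairs = np.concatenate([z[:-1], z[1:]], axis=1)  # (n, 2d)
            logits = model.classifier.forward(pairs, True)
            logp = log_softmax(logits)
            loss, dlogits = nll_loss_grad(logp, labels)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss {loss}")

            dpairs = model.classifier.backward(dlogits, need_dx=True)
            d = model.config.embedding_dim
            dz = np.zeros_like(z)
            dz[:-1] += dpairs[:, :d]
            dz[1:] += dpairs[:, d:]
            model.trunk.backward(dz, need_dx=False)
            opt.step()

            losses.append(loss)
            hits += int((logits.argmax(axis=1) == labels).sum())
            seen += len(labels)
            history.pairs_consumed += len(labels)
        history.epoch_loss.append(float(np.mean(losses)))
        history.epoch_accuracy.append(hits / seen)
    assert history.pairs_consumed == cfg.total_pairs
    return history


# ---------------------------------------------------------------------------
# evaluation

def action_accuracy(model: PerceptionModel,
                    records: Sequence[scenes.ActionRecord]) -> float:
    """Fraction of correctly predicted actions over a record list."""
    frames, labels = _sequence_arrays(records)
    z = model.embed(frames)
    logits = model.classifier.forward(np.concatenate([z[:-1], z[1:]], axis=1), False)
    return float((logits.argmax(axis=1) == labels).mean())


def evaluate_action_error_by_count(model: PerceptionModel,
                                   test_records: Sequence[Sequence[scenes.ActionRecord]]):
    """Per-before-count action error rates with 95% Bayesian intervals.

    ``test_records`` is a list of episodes.  Returns a DataFrame indexed by
    the object count of the before-image: error rate, interval, sample size.
    """
    import pandas as pd

    from .psychophys import bayesian_binomial_ci

    counts, errors = [], []
    for records in test_records:
        frames, labels = _sequence_arrays(records)
        z = model.embed(frames)
        logits = model.classifier.forward(np.concatenate([z[:-1], z[1:]], axis=1), False)
        pred = logits.argmax(axis=1)
        counts.extend(r.state_before.count for r in records)
        errors.extend((pred != labels).tolist())
    df = pd.DataFrame({"count": counts, "error": np.asarray(errors, dtype=int)})
    rows = []
    for c, grp in df.groupby("count"):
        n, k = len(grp), int(grp["error"].sum())
        ci = bayesian_binomial_ci(k, n)
        rows.append({"count": c, "n": n, "errors": k, "error_rate": k / n,
                     "ci_lower": ci.lower, "ci_upper": ci.upper})
    out = pd.DataFrame(rows).set_index("count")
    if out.empty:
        raise ValueError("no test records supplied")
    return out
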