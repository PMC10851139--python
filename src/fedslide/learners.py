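"""Patch classifiers and slide-level inference.

The unit of training is the patch; the unit of evaluation is the slide.  A
backbone maps a patch to two class logits, training minimises unweighted
softmax cross-entropy with SGD (momentum 0.9) under a 1-cycle learning-rate
policy, and a slide's melanoma probability is the arithmetic mean of its
kept patches' melanoma (class-1) probabilities.

Backbones
---------
``tiny_cnn``
    Three conv/ReLU/pool blocks plus a linear head, ~6k parameters.  The
    default: small enough that desk-scale experiments train in seconds on
    one CPU while still separating texture classes.
``resnet18``
    The standard 18-layer residual network with a 2-class head, randomly
    initialised.  Provided for structural parity with larger studies; no
    pretrained weights ship with the package.
``linear_probe``
    An affine score on seven fixed colour/texture features.  Its prediction
    is *linear in the parameters*, which makes it the exact test vehicle
    for weight-averaging identities.

Weights travel as :class:`ModelWeights`, a named collection of numpy arrays
with a strict mergeability contract (same names, same shapes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _nn
from .errors import (
    ConfigurationError,
    ContractError,
    UndefinedPredictionError,
    ValidationError,
)
from .preprocessing import PatchSet

__all__ = [
    "ModelWeights",
    "TrainConfig",
    "build_backbone",
    "one_cycle_lr",
    "sample_epoch_patches",
    "train_local",
    "LocalTrainer",
    "predict_patch_probs",
    "predict_slide",
    "patch_features",
    "save_weights",
    "load_weights",
    "PatchCNNSlideClassifier",
]

BACKBONES = ("tiny_cnn", "resnet18", "linear_probe")

WEIGHTS_FORMAT_VERSION = 1


@dataclass
class ModelWeights:
    """Named collection of parameter arrays exchanged between sites.

    Two instances are mergeable iff their entry names and array shapes match
    exactly; merging is a weighted average entry by entry (see
    :mod:`fedslide.federation`).
    """

    entries: dict  # name -> np.ndarray
    meta: dict = field(default_factory=dict)

    def copy(self) -> "ModelWeights":
        return ModelWeights(
            {k: v.copy() for k, v in self.entries.items()}, dict(self.meta)
        )

    def mergeable_with(self, other: "ModelWeights") -> bool:
        if list(self.entries) != list(other.entries):
            return False
        return all(
            self.entries[k].shape == other.entries[k].shape for k in self.entries
        )

    def n_params(self) -> int:
        return sum(v.size for v in self.entries.values())

    def allclose(self, other: "ModelWeights", **kw) -> bool:
        return self.mergeable_with(other) and all(
            np.allclose(self.entries[k], other.entries[k], **kw) for k in self.entries
        )

    @property
    def backbone(self) -> str:
        return self.meta.get("backbone", "tiny_cnn")


@dataclass
class TrainConfig:
    """Hyperparameters of one local training run.

    ``per_wsi_fraction`` is the fraction of each slide's kept patches drawn
    (without replacement, fresh every epoch) into the epoch's training pool.
    """

    seed: int
    lr_max: float = 0.05
    epochs: int = 4
    per_wsi_fraction: float = 0.5
    batch_size: int = 32
    backbone: str = "tiny_cnn"
    momentum: float = 0.9
    lr_div: float = 25.0

    def __post_init__(self):
        if self.lr_max <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ConfigurationError("lr_max, epochs, batch_size must be positive")
        if not 0 < self.per_wsi_fraction <= 1:
            raise ConfigurationError("per_wsi_fraction must be in (0, 1]")
        if self.backbone not in BACKBONES:
            raise ConfigurationError(f"unknown backbone {self.backbone!r}")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")


def _make_net(backbone: str, rng=None) -> _nn.Net:
    if backbone == "tiny_cnn":
        return _nn.Net(
            [
                _nn.Conv2d(3, 8, 3, 1, 1, rng),
                _nn.ReLU(),
                _nn.MaxPool2d(2),
                _nn.Conv2d(8, 16, 3, 1, 1, rng),
                _nn.ReLU(),
                _nn.MaxPool2d(2),
                _nn.Conv2d(16, 32, 3, 1, 1, rng),
                _nn.ReLU(),
                _nn.GlobalAvgPool(),
                _nn.Linear(32, 2, rng),
            ]
        )
    if backbone == "resnet18":
        layers = [
            _nn.Conv2d(3, 64, 7, 2, 3, rng),
            _nn.BatchNorm2d(64),
            _nn.ReLU(),
            _nn.MaxPool2d(3, 2, 1),
        ]
        widths = [(64, 64, 1), (64, 128, 2), (128, 256, 2), (256, 512, 2)]
        for c_in, c_out, stride in widths:
            layers.append(_nn.BasicBlock(c_in, c_out, stride, rng))
            layers.append(_nn.BasicBlock(c_out, c_out, 1, rng))
        layers += [_nn.GlobalAvgPool(), _nn.Linear(512, 2, rng)]
        return _nn.Net(layers)
    raise ConfigurationError(f"unknown backbone {backbone!r}")


def build_backbone(name: str, seed: int) -> ModelWeights:
    """Deterministically initialise a backbone's weights.

    The same ``(name, seed)`` always yields identical arrays.
    """
    if name not in BACKBONES:
        raise ConfigurationError(f"unknown backbone {name!r}; choose from {BACKBONES}")
    rng = np.random.default_rng(seed)
    if name == "linear_probe":
        entries = {
            "weight": (rng.standard_normal(7) * 0.1).astype(np.float64),
            "bias": np.zeros(1, dtype=np.float64),
        }
    else:
        entries = _make_net(name, rng).state_dict()
    return ModelWeights(entries, {"backbone": name, "init_seed": int(seed)})


def one_cycle_lr(
    step: int, total_steps: int, lr_max: float, div: float = 25.0, final_div: float = 100.0
) -> float:
    """1-cycle learning-rate policy.

    Linear ramp from ``lr_max/div`` up to ``lr_max`` over the first half of
    training, then cosine annealing down to ``lr_max/(div*final_div)`` over
    the second half.  The maximum is attained exactly at
    ``step == total_steps // 2``.
    """
    if not 0 <= step < total_steps:
        raise ValidationError(f"step {step} outside [0, {total_steps})")
    half = total_steps // 2
    lr_start = lr_max / div
    lr_end = lr_max / (div * final_div)
    if step <= half:
        if half == 0:
            return lr_max
        return lr_start + (lr_max - lr_start) * (step / half)
    t = (step - half) / (total_steps - 1 - half)
    return lr_end + (lr_max - lr_end) * 0.5 * (1.0 + math.cos(math.pi * t))


def sample_epoch_patches(ps: PatchSet, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Sample ``ceil(fraction * n_kept)`` kept-patch indices without replacement.

    The ceiling guarantees at least one patch whenever the slide has any
    kept patches.  ``fraction=1`` returns all kept indices in shuffled order.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    kept_idx = np.flatnonzero(ps.kept)
    if kept_idx.size == 0:
        raise ValidationError(f"slide {ps.slide_id} has no kept patches")
    k = math.ceil(fraction * kept_idx.size)
    return rng.choice(kept_idx, size=k, replace=False)


def _patches_to_input(patches: np.ndarray) -> np.ndarray:
    """uint8 HWC patches -> float32 NCHW in [-0.5, 0.5]."""
    x = patches.astype(np.float32) / 255.0 - 0.5
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def patch_features(patches: np.ndarray) -> np.ndarray:
    """Fixed 7-dim colour/texture features used by the linear probe.

    Per-channel means and standard deviations (6) plus the mean local
    variance of the grayscale image over 3x3 neighbourhoods (1), all on the
    [0, 1] intensity scale.
    """
    from scipy import ndimage

    x = patches.astype(np.float64) / 255.0
    means = x.mean(axis=(1, 2))
    stds = x.std(axis=(1, 2))
    gray = x @ np.array([0.299, 0.587, 0.114])
    local_var = np.empty(len(x))
    for i, g in enumerate(gray):
        mu = ndimage.uniform_filter(g, 3, mode="reflect")
        mu2 = ndimage.uniform_filter(g * g, 3, mode="reflect")
        local_var[i] = (mu2 - mu * mu).mean()
    return np.column_stack([means, stds, local_var * 100.0])


class LocalTrainer:
    """Resumable SGD training state for one data shard.

    Holds the RNG, the epoch buffer, the optimizer velocity and the step
    counter so that training can be run in interrupted intervals (as the
    federated protocol requires) and still produce *bitwise* the same weight
    trajectory as one uninterrupted run — the identity the single-site
    federation check asserts.
    """

    def __init__(self, data, cfg: TrainConfig, total_steps: int | None = None,
                 lr_schedule=None):
        if not data:
            raise ValidationError("empty training data")
        usable = []
        for ps, label in data:
            if ps.n_kept == 0:
                warnings.warn(f"slide {ps.slide_id} has no kept patches; skipped")
                continue
            usable.append((ps, int(label)))
        if not usable:
            raise ValidationError("no slide in the shard has kept patches")
        self.data = usable
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        per_epoch = sum(
            math.ceil(cfg.per_wsi_fraction * ps.n_kept) for ps, _ in usable
        )
        self.steps_per_epoch = max(1, math.ceil(per_epoch / cfg.batch_size))
        self.total_steps = (
            int(total_steps) if total_steps is not None else cfg.epochs * self.steps_per_epoch
        )
        self.lr_schedule = lr_schedule or (
            lambda s: one_cycle_lr(s, self.total_steps, cfg.lr_max, cfg.lr_div)
        )
        self.step = 0
        self._epoch_batches = []
        self._velocity = None
        self.last_epoch_loss = None

    # -- epoch assembly -------------------------------------------------
    def _new_epoch(self):
        xs, ys = [], []
        for ps, label in self.data:
            idx = sample_epoch_patches(ps, self.cfg.per_wsi_fraction, self.rng)
            xs.append(ps.patches[idx])
            ys.append(np.full(len(idx), label, dtype=np.int64))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        perm = self.rng.permutation(len(x))
        x, y = x[perm], y[perm]
        b = self.cfg.batch_size
        self._epoch_batches = [
            (x[i : i + b], y[i : i + b]) for i in range(0, len(x), b)
        ][::-1]

    def _next_batch(self):
        if not self._epoch_batches:
            self._new_epoch()
        return self._epoch_batches.pop()

    # -- training -------------------------------------------------------
    def run(self, weights: ModelWeights, n_steps: int | None = None) -> ModelWeights:
        """Advance training by ``n_steps`` optimizer steps from ``weights``."""
        n = (self.total_steps - self.step) if n_steps is None else int(n_steps)
        if n == 0:
            return weights.copy()
        if weights.backbone != self.cfg.backbone:
            raise ContractError(
                f"weights backbone {weights.backbone!r} != config {self.cfg.backbone!r}"
            )
        if self.cfg.backbone == "linear_probe":
            return self._run_linear(weights, n)
        net = _make_net(self.cfg.backbone)
        try:
            net.load_state_dict(weights.entries)
        except KeyError as exc:
            raise ContractError(f"weights do not match backbone: missing {exc}") from exc
        opt = _nn.SGD(net, self.cfg.momentum)
        if self._velocity is not None:
            opt.velocity = self._velocity
        losses = []
        for _ in range(n):
            xb, yb = self._next_batch()
            logits = net.forward(_patches_to_input(xb), train=True)
            loss, dlogits = _nn.softmax_cross_entropy(logits, yb)
            net.backward(dlogits)
            opt.step(self.lr_schedule(self.step))
            self.step += 1
            losses.append(loss)
        self._velocity = opt.velocity
        self.last_epoch_loss = float(np.mean(losses))
        meta = dict(weights.meta)
        meta["trained_steps"] = meta.get("trained_steps", 0) + n
        return ModelWeights(net.state_dict(), meta)

    def _run_linear(self, weights: ModelWeights, n: int) -> ModelWeights:
        w = weights.entries["weight"].copy()
        b = weights.entries["bias"].copy()
        vel_w = np.zeros_like(w)
        vel_b = np.zeros_like(b)
        if self._velocity is not None:
            vel_w, vel_b = self._velocity
        losses = []
        for _ in range(n):
            xb, yb = self._next_batch()
            phi = patch_features(xb)
            score = phi @ w + b[0]
            p = 1.0 / (1.0 + np.exp(-score))
            losses.append(float(-np.mean(yb * np.log(np.clip(p, 1e-12, None))
                                         + (1 - yb) * np.log(np.clip(1 - p, 1e-12, None)))))
            g = (p - yb) / len(yb)
            lr = self.lr_schedule(self.step)
            vel_w = self.cfg.momentum * vel_w - lr * (phi.T @ g)
            vel_b = self.cfg.momentum * vel_b - lr * g.sum()
            w += vel_w
            b += vel_b
            self.step += 1
        self._velocity = (vel_w, vel_b)
        self.last_epoch_loss = float(np.mean(losses))
        return ModelWeights({"weight": w, "bias": b}, dict(weights.meta))


def train_local(
    w: ModelWeights,
    data,
    cfg: TrainConfig,
    n_steps: int | None = None,
) -> ModelWeights:
    """Train a model on one shard of ``(PatchSet, label)`` pairs.

    Runs ``cfg.epochs`` full epochs, or exactly ``n_steps`` optimizer steps
    when given (the federated protocol's interval mode).  Fully
    deterministic given the config seed and data order; ``n_steps=0``
    returns an unchanged copy of the input weights.
    """
    if n_steps == 0:
        return w.copy()
    trainer = LocalTrainer(data, cfg, total_steps=n_steps)
    return trainer.run(w, n_steps)


def predict_patch_probs(w: ModelWeights, patches: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Per-patch melanoma probability (softmax class-1) for an array of patches.

    For the ``linear_probe`` backbone this is the raw affine score, which is
    linear in the parameters by design.
    """
    if w.backbone == "linear_probe":
        phi = patch_features(patches)
        return phi @ w.entries["weight"] + w.entries["bias"][0]
    net = _make_net(w.backbone)
    net.load_state_dict(w.entries)
    out = []
    for i in range(0, len(patches), chunk):
        logits = net.forward(_patches_to_input(patches[i : i + chunk]), train=False)
        out.append(_nn.softmax(logits)[:, 1])
    return np.concatenate(out)


def predict_slide(w: ModelWeights, ps: PatchSet) -> float:
    """Slide-level probability: mean class-1 probability over kept patches.

    Invariant to patch order; raises if the slide has no kept patches.
    """
    if ps.n_kept == 0:
        raise UndefinedPredictionError(
            f"slide {ps.slide_id} has no kept patches; prediction undefined"
        )
    return float(predict_patch_probs(w, ps.kept_patches()).mean())


def save_weights(w: ModelWeights, path) -> None:
    """Serialize weights to a single-file named-array container (.npz)."""
    meta = dict(w.meta, _format_version=WEIGHTS_FORMAT_VERSION)
    np.savez(
        path,
        __meta__=np.frombuffer(repr(meta).encode(), dtype=np.uint8),
        **w.entries,
    )


def load_weights(path) -> ModelWeights:
    import ast

    with np.load(path) as data:
        meta = ast.literal_eval(bytes(data["__meta__"]).decode())
        entries = {k: data[k] for k in data.files if k != "__meta__"}
    meta.pop("_format_version", None)
    return ModelWeights(entries, meta)


class PatchCNNSlideClassifier(ClassifierMixin, BaseEstimator):
    """Slide-level melanoma classifier trained on patches of one shard.

    scikit-learn estimator interface: ``X`` is a list of
    :class:`~fedslide.preprocessing.PatchSet` (one per slide) and ``y`` the
    slide labels.  Following the sklearn convention, the positive
    (melanoma) class is ``classes_[1]``; pass integer labels 0/1 or sort
    your label strings accordingly.

    Attributes
    ----------
    weights_ : ModelWeights
        Trained backbone weights.
    classes_ : ndarray of shape (2,)
        Label values; column order of :meth:`predict_proba`.
    n_slides_ : int
        Number of training slides actually used.
    """

    def __init__(self, backbone="tiny_cnn", lr_max=0.05, epochs=4,
                 per_wsi_fraction=0.5, batch_size=32, momentum=0.9, seed=0):
        self.backbone = backbone
        self.lr_max = lr_max
        self.epochs = epochs
        self.per_wsi_fraction = per_wsi_fraction
        self.batch_size = batch_size
        self.momentum = momentum
        self.seed = seed

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            seed=self.seed,
            lr_max=self.lr_max,
            epochs=self.epochs,
            per_wsi_fraction=self.per_wsi_fraction,
            batch_size=self.batch_size,
            backbone=self.backbone,
            momentum=self.momentum,
        )

    def _encode_y(self, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValidationError(
                f"need exactly 2 classes, got {list(self.classes_)}"
            )
        return (y == self.classes_[1]).astype(int)

    def fit(self, X, y, **fit_params):
        y01 = self._encode_y(y)
        cfg = self._train_config()
        w0 = build_backbone(self.backbone, self.seed)
        self.weights_ = train_local(w0, list(zip(X, y01)), cfg)
        self.n_slides_ = len(X)
        return self

    def predict_proba(self, X):
        p1 = np.array([predict_slide(self.weights_, ps) for ps in X])
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]
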