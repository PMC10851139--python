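"""Federated averaging simulated on one computational unit.

The protocol: every round, each site advances the current global model by a
site-specific number of local SGD steps (its synchronization interval,
proportional to its data size), the resulting per-site weights are merged
by a data-proportional weighted average, and the merged model is
redistributed.  Sites train sequentially in site order; a transport layer
is out of scope.

Two design points worth knowing:

* the 1-cycle learning-rate schedule spans the *whole* federated run per
  site (``n_rounds * steps_k`` steps), avoiding a learning-rate restart at
  every synchronization;
* per-site optimizer state (RNG, momentum velocity, epoch buffer) persists
  across rounds, so a degenerate single-site federation is bitwise
  identical to one uninterrupted local training run.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ConfigurationError, ContractError, ValidationError
from .learners import (
    LocalTrainer,
    ModelWeights,
    TrainConfig,
    build_backbone,
    one_cycle_lr,
    predict_slide,
)

__all__ = [
    "FederationConfig",
    "MergeWeights",
    "compute_schedule",
    "site_seed",
    "merge_weights",
    "run_federated_training",
    "FederatedSlideClassifier",
]


@dataclass
class MergeWeights:
    """Per-site convex merge coefficients (non-negative, sum to 1)."""

    values: tuple

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if any(v < 0 for v in vals):
            raise ValidationError("merge weights must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-12:
            raise ValidationError(f"merge weights must sum to 1, got {sum(vals)}")
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_sizes(cls, sizes) -> "MergeWeights":
        sizes = np.asarray(sizes, dtype=float)
        if (sizes <= 0).any():
            raise ValidationError("sizes must be positive")
        return cls(tuple(sizes / sizes.sum()))

    def __len__(self):
        return len(self.values)


@dataclass
class FederationConfig:
    """Settings of one federated run.

    ``sync_factor`` converts a site's data size into its per-round local
    step count: ``steps_k = max(1, round(sync_factor * n_k))``.
    ``weight_by`` selects whether merge weights (and the schedule) use
    slide counts (default, robust to per-slide patch variance) or patch
    counts.
    """

    train_cfg: TrainConfig
    sync_factor: float = 0.25
    n_rounds: int = 4
    weight_by: str = "slides"

    def __post_init__(self):
        if self.sync_factor <= 0:
            raise ConfigurationError("sync_factor must be positive")
        if self.n_rounds < 0:
            raise ConfigurationError("n_rounds must be >= 0")
        if self.weight_by not in ("slides", "patches"):
            raise ConfigurationError("weight_by must be 'slides' or 'patches'")


def site_seed(global_seed: int, site_index: int) -> int:
    """Deterministic per-site training seed derived from the global seed.

    Public so that identities like "single-site federation equals one
    uninterrupted local run" can be reproduced exactly outside the loop.
    """
    return int((global_seed * 1_000_003 + site_index * 7919 + 1) % (2**31))


def compute_schedule(site_sizes, sync_factor: float) -> list:
    """Per-site local steps per round: ``max(1, round(sync_factor * n_k))``."""
    steps = []
    for n in site_sizes:
        if n <= 0:
            raise ValidationError("site sizes must be positive")
        steps.append(max(1, int(np.floor(sync_factor * n + 0.5))))
    return steps


def merge_weights(models, mw: MergeWeights) -> ModelWeights:
    """Convex combination of parameter arrays, entry by entry.

    All models must expose identical entry names and shapes; the output
    preserves them exactly.  Commutative under a simultaneous permutation
    of (models, weights), and the identity when all members are equal.
    """
    models = list(models)
    if not models:
        raise ValidationError("no models to merge")
    if len(models) != len(mw):
        raise ContractError(f"{len(models)} models but {len(mw)} merge weights")
    first = models[0]
    for m in models[1:]:
        if not first.mergeable_with(m):
            raise ContractError("models are not mergeable: names/shapes differ")
    entries = {}
    for name in first.entries:
        acc = np.zeros_like(first.entries[name], dtype=np.float64)
        for m, w in zip(models, mw.values):
            acc += w * m.entries[name]
        entries[name] = acc.astype(first.entries[name].dtype)
    meta = dict(first.meta)
    meta["merged_from"] = len(models)
    return ModelWeights(entries, meta)


def run_federated_training(
    shards,
    cfg: FederationConfig,
    initial: ModelWeights | None = None,
    log_path=None,
    validation=None,
) -> ModelWeights:
    """Run the full federated loop and return the final global model.

    Parameters
    ----------
    shards:
        Per-site training data: a list of lists of ``(PatchSet, label)``.
        Empty shards are dropped with a warning and the merge weights
        renormalized over the remaining sites.
    cfg:
        Federation settings; ``cfg.train_cfg.seed`` seeds everything.
    initial:
        Starting global weights; a fresh backbone is built when omitted.
    log_path:
        Optional JSON-lines round log (round, per-site steps, merge
        weights, optional validation AUROC).
    validation:
        Optional ``(patchsets, labels)`` pair scored after each merge.
    """
    shards = list(shards)
    live = [(i, s) for i, s in enumerate(shards) if len(s) > 0]
    dropped = [i for i, s in enumerate(shards) if len(s) == 0]
    if dropped:
        warnings.warn(f"dropping empty shards at positions {dropped}")
    if not live:
        raise ValidationError("all shards are empty")

    tc = cfg.train_cfg
    if cfg.weight_by == "patches":
        sizes = [sum(ps.n_kept for ps, _ in s) for _, s in live]
    else:
        sizes = [len(s) for _, s in live]
    steps = compute_schedule(sizes, cfg.sync_factor)
    mw = MergeWeights.from_sizes(sizes)

    global_model = initial.copy() if initial is not None else build_backbone(tc.backbone, tc.seed)

    # One persistent trainer per site; its 1-cycle schedule spans the run.
    trainers = []
    for k, (orig_idx, shard) in enumerate(live):
        site_cfg = TrainConfig(
            seed=site_seed(tc.seed, orig_idx),
            lr_max=tc.lr_max,
            epochs=tc.epochs,
            per_wsi_fraction=tc.per_wsi_fraction,
            batch_size=tc.batch_size,
            backbone=tc.backbone,
            momentum=tc.momentum,
            lr_div=tc.lr_div,
        )
        total_k = max(1, cfg.n_rounds * steps[k])
        trainers.append(
            LocalTrainer(
                shard,
                site_cfg,
                total_steps=total_k,
                lr_schedule=lambda s, tk=total_k: one_cycle_lr(
                    min(s, tk - 1), tk, tc.lr_max, tc.lr_div
                ),
            )
        )

    log_fh = open(log_path, "w") if log_path else None
    try:
        for rnd in range(cfg.n_rounds):
            locals_ = [
                trainer.run(global_model, steps[k])
                for k, trainer in enumerate(trainers)
            ]
            global_model = merge_weights(locals_, mw)
            if log_fh:
                entry = {
                    "round": rnd,
                    "site_steps": steps,
                    "merge_weights": list(mw.values),
                }
                if validation is not None:
                    from .evaluation import auroc

                    ps_list, labels = validation
                    probs = [predict_slide(global_model, ps) for ps in ps_list]
                    entry["validation_auroc"] = auroc(labels, probs)
                log_fh.write(json.dumps(entry) + "\n")
    finally:
        if log_fh:
            log_fh.close()
    return global_model


class FederatedSlideClassifier(ClassifierMixin, BaseEstimator):
    """Slide classifier trained with simulated federated averaging.

    ``fit(X, y, sites=...)`` takes one :class:`PatchSet` per slide plus a
    per-slide site id; slides of each site form one federation shard.  The
    positive class is ``classes_[1]`` (sklearn convention).

    Attributes: ``weights_`` (final global model), ``classes_``,
    ``merge_weights_``, ``site_steps_``.
    """

    def __init__(self, backbone="tiny_cnn", lr_max=0.05, epochs=4,
                 per_wsi_fraction=0.5, batch_size=32, momentum=0.9,
                 sync_factor=0.25, n_rounds=4, weight_by="slides", seed=0):
        self.backbone = backbone
        self.lr_max = lr_max
        self.epochs = epochs
        self.per_wsi_fraction = per_wsi_fraction
        self.batch_size = batch_size
        self.momentum = momentum
        self.sync_factor = sync_factor
        self.n_rounds = n_rounds
        self.weight_by = weight_by
        self.seed = seed

    def fit(self, X, y, sites=None):
        if sites is None:
            raise ValidationError("FederatedSlideClassifier.fit requires sites=")
        y = np.asarray(y)
        sites = np.asarray(sites)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValidationError("need exactly 2 classes")
        y01 = (y == self.classes_[1]).astype(int)
        shards = []
        for site in np.unique(sites):
            idx = np.flatnonzero(sites == site)
            shards.append([(X[i], y01[i]) for i in idx])
        tc = TrainConfig(
            seed=self.seed, lr_max=self.lr_max, epochs=self.epochs,
            per_wsi_fraction=self.per_wsi_fraction, batch_size=self.batch_size,
            backbone=self.backbone, momentum=self.momentum,
        )
        fc = FederationConfig(
            train_cfg=tc, sync_factor=self.sync_factor,
            n_rounds=self.n_rounds, weight_by=self.weight_by,
        )
        sizes = [len(s) for s in shards]
        self.site_steps_ = compute_schedule(sizes, self.sync_factor)
        self.merge_weights_ = MergeWeights.from_sizes(sizes)
        self.weights_ = run_federated_training(shards, fc)
        return self

    def predict_proba(self, X):
        p1 = np.array([predict_slide(self.weights_, ps) for ps in X])
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]
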