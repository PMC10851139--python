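"""Centralized, leave-one-site-out and ensemble baselines.

All three reuse the local training loop from :mod:`fedslide.learners`:

* centralized ("Hfull"): pool every site's training slides into one shard
  and train once;
* leave-one-site-out ("H1".."H5"): centralized training with one site's
  data excluded;
* ensemble: one independent model per site, slide probabilities averaged
  across members at inference.

Site interleaving within batches comes from the per-epoch patch-level
shuffle inside the training loop, so pooling is a plain concatenation and
a one-shard pool trains identically to a plain local run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ConfigurationError, ValidationError
from .learners import (
    ModelWeights,
    TrainConfig,
    build_backbone,
    predict_slide,
    train_local,
)

__all__ = [
    "ExperimentPlan",
    "train_centralized",
    "train_leave_one_out",
    "train_ensemble",
    "ensemble_predict",
    "CentralizedSlideClassifier",
    "LeaveOneSiteOutSlideClassifier",
    "EnsembleSlideClassifier",
]


@dataclass
class ExperimentPlan:
    """Which strategy trains on which sites, and what is held out.

    ``external_site`` must not appear among ``train_sites``; the holdout
    test set is drawn only from training sites.
    """

    strategy: str  # federated | centralized_full | leave_one_out | ensemble
    train_sites: tuple
    external_site: int
    holdout_fraction: float = 0.15
    excluded_site: int | None = None

    def __post_init__(self):
        if self.strategy not in (
            "federated", "centralized_full", "leave_one_out", "ensemble"
        ):
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        if self.external_site in self.train_sites:
            raise ConfigurationError("external_site must not be a training site")
        if not 0 < self.holdout_fraction < 1:
            raise ConfigurationError("holdout_fraction must be in (0, 1)")
        if self.strategy == "leave_one_out" and self.excluded_site is None:
            raise ConfigurationError("leave_one_out requires excluded_site")


def _pool(shards):
    pooled = []
    for shard in shards:
        pooled.extend(shard)
    return pooled


def train_centralized(shards, cfg: TrainConfig,
                      initial: ModelWeights | None = None) -> ModelWeights:
    """Pool all shards and train one model on the union."""
    shards = list(shards)
    if not shards or all(len(s) == 0 for s in shards):
        raise ValidationError("empty training pool")
    pooled = _pool(shards)
    w0 = initial if initial is not None else build_backbone(cfg.backbone, cfg.seed)
    return train_local(w0, pooled, cfg)


def train_leave_one_out(shards: dict, excluded_site, cfg: TrainConfig) -> ModelWeights:
    """Centralized training on every shard except ``excluded_site``.

    ``shards`` maps site id to that site's list of ``(PatchSet, label)``.
    """
    if excluded_site not in shards:
        raise ValidationError(f"site {excluded_site!r} not among shards")
    rest = [shard for site, shard in shards.items() if site != excluded_site]
    if not rest:
        raise ValidationError("cannot exclude the only shard")
    return train_centralized(rest, cfg)


def train_ensemble(shards, cfgs) -> list:
    """Train one independent member per shard with its own config/seed.

    Empty shards are skipped with a warning (the member is simply absent).
    """
    shards, cfgs = list(shards), list(cfgs)
    if len(shards) != len(cfgs):
        raise ValidationError("need one TrainConfig per shard")
    members = []
    for i, (shard, cfg) in enumerate(zip(shards, cfgs)):
        if len(shard) == 0:
            warnings.warn(f"ensemble member {i} skipped: empty shard")
            continue
        w0 = build_backbone(cfg.backbone, cfg.seed)
        members.append(train_local(w0, shard, cfg))
    if not members:
        raise ValidationError("all ensemble shards were empty")
    return members


def ensemble_predict(models, ps) -> float:
    """Mean of member slide probabilities; order-invariant, bounded by members."""
    models = list(models)
    if not models:
        raise ValidationError("empty model list")
    return float(np.mean([predict_slide(m, ps) for m in models]))


class _SlideClassifierBase(ClassifierMixin, BaseEstimator):
    """Shared fit plumbing: label encoding and per-site shard assembly."""

    def _encode(self, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValidationError("need exactly 2 classes")
        return (y == self.classes_[1]).astype(int)

    def _shards_by_site(self, X, y01, sites):
        sites = np.asarray(sites)
        return {
            site: [(X[i], y01[i]) for i in np.flatnonzero(sites == site)]
            for site in np.unique(sites)
        }

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            seed=self.seed, lr_max=self.lr_max, epochs=self.epochs,
            per_wsi_fraction=self.per_wsi_fraction, batch_size=self.batch_size,
            backbone=self.backbone, momentum=self.momentum,
        )

    def predict_proba(self, X):
        p1 = np.array([self._slide_prob(ps) for ps in X])
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


class CentralizedSlideClassifier(_SlideClassifierBase):
    """The pooled-data baseline ("Hfull" when trained on all sites)."""

    def __init__(self, backbone="tiny_cnn", lr_max=0.05, epochs=4,
                 per_wsi_fraction=0.5, batch_size=32, momentum=0.9, seed=0):
        self.backbone = backbone
        self.lr_max = lr_max
        self.epochs = epochs
        self.per_wsi_fraction = per_wsi_fraction
        self.batch_size = batch_size
        self.momentum = momentum
        self.seed = seed

    def fit(self, X, y, sites=None):
        y01 = self._encode(y)
        self.weights_ = train_centralized([list(zip(X, y01))], self._train_config())
        self.n_slides_ = len(X)
        return self

    def _slide_prob(self, ps):
        return predict_slide(self.weights_, ps)


class LeaveOneSiteOutSlideClassifier(_SlideClassifierBase):
    """Centralized training with one site excluded ("H<k>")."""

    def __init__(self, excluded_site=None, backbone="tiny_cnn", lr_max=0.05,
                 epochs=4, per_wsi_fraction=0.5, batch_size=32, momentum=0.9,
                 seed=0):
        self.excluded_site = excluded_site
        self.backbone = backbone
        self.lr_max = lr_max
        self.epochs = epochs
        self.per_wsi_fraction = per_wsi_fraction
        self.batch_size = batch_size
        self.momentum = momentum
        self.seed = seed

    def fit(self, X, y, sites=None):
        if sites is None:
            raise ValidationError("LeaveOneSiteOutSlideClassifier.fit requires sites=")
        y01 = self._encode(y)
        shards = self._shards_by_site(X, y01, sites)
        self.weights_ = train_leave_one_out(
            shards, self.excluded_site, self._train_config()
        )
        return self

    def _slide_prob(self, ps):
        return predict_slide(self.weights_, ps)


class EnsembleSlideClassifier(_SlideClassifierBase):
    """One member per site, probabilities averaged at inference.

    ``member_params`` optionally maps site id to per-member hyperparameter
    overrides (the per-site tuning hook); otherwise members share the
    estimator's settings with site-distinct seeds.
    """

    def __init__(self, backbone="tiny_cnn", lr_max=0.05, epochs=4,
                 per_wsi_fraction=0.5, batch_size=32, momentum=0.9, seed=0,
                 member_params=None):
        self.backbone = backbone
        self.lr_max = lr_max
        self.epochs = epochs
        self.per_wsi_fraction = per_wsi_fraction
        self.batch_size = batch_size
        self.momentum = momentum
        self.seed = seed
        self.member_params = member_params

    def fit(self, X, y, sites=None):
        if sites is None:
            raise ValidationError("EnsembleSlideClassifier.fit requires sites=")
        y01 = self._encode(y)
        shards = self._shards_by_site(X, y01, sites)
        cfgs = []
        for j, site in enumerate(sorted(shards)):
            over = (self.member_params or {}).get(site, {})
            cfgs.append(
                TrainConfig(
                    seed=over.get("seed", self.seed + 1000 * (j + 1)),
                    lr_max=over.get("lr_max", self.lr_max),
                    epochs=over.get("epochs", self.epochs),
                    per_wsi_fraction=over.get("per_wsi_fraction", self.per_wsi_fraction),
                    batch_size=over.get("batch_size", self.batch_size),
                    backbone=self.backbone,
                    momentum=self.momentum,
                )
            )
        self.members_ = train_ensemble(
            [shards[s] for s in sorted(shards)], cfgs
        )
        self.member_sites_ = sorted(shards)
        return self

    def _slide_prob(self, ps):
        return ensemble_predict(self.members_, ps)
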