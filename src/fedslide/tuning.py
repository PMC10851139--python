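"""Hyperparameter tuning: validation splits and a TPE search loop.

The tuning protocol mirrors the benchmark design: 30% of the training
data (lesion-level, label-stratified within each site) serves as the
validation set, and a tree-structured Parzen estimator (TPE) proposes
hyperparameters to maximise validation slide-level AUROC.  Every strategy
being compared must receive the same number of optimisation trials; the
fairness check below enforces that.

The TPE sampler is a compact in-package implementation: after a short
random start-up phase, observed trials are split into a good fraction
(top ``gamma`` by objective) and the rest, each parameter is modelled with
a one-dimensional Gaussian kernel density in its transformed space (log
for log-uniform parameters), and the candidate maximising the good/bad
density ratio is evaluated next.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "SearchSpace",
    "make_validation_split",
    "tpe_search",
    "TuningResult",
    "check_equal_trials",
]


@dataclass
class SearchSpace:
    """Ranges for the tuned hyperparameters.

    ``lr_max`` and ``sync_factor`` are searched log-uniformly, ``epochs``
    as an integer range, ``per_wsi_fraction`` uniformly.  ``sync_factor``
    is present only when tuning the federated strategy.
    """

    lr_max: tuple = (1e-3, 0.3)
    epochs: tuple = (2, 8)
    per_wsi_fraction: tuple = (0.2, 1.0)
    sync_factor: tuple | None = None

    def __post_init__(self):
        for name in ("lr_max", "epochs", "per_wsi_fraction", "sync_factor"):
            rng = getattr(self, name)
            if rng is None:
                continue
            lo, hi = rng
            if not lo < hi:
                raise ConfigurationError(f"degenerate range for {name}: {rng}")
            if name in ("lr_max", "sync_factor") and lo <= 0:
                raise ConfigurationError(f"{name} range must be positive")

    def dimensions(self):
        dims = [
            ("lr_max", float(self.lr_max[0]), float(self.lr_max[1]), "log"),
            ("epochs", float(self.epochs[0]), float(self.epochs[1]), "int"),
            ("per_wsi_fraction", float(self.per_wsi_fraction[0]),
             float(self.per_wsi_fraction[1]), "uniform"),
        ]
        if self.sync_factor is not None:
            dims.append(
                ("sync_factor", float(self.sync_factor[0]),
                 float(self.sync_factor[1]), "log")
            )
        return dims


def _label_of(item):
    if hasattr(item, "label"):
        return item.label
    if isinstance(item, (tuple, list)) and len(item) >= 2:
        return item[1]
    raise ValidationError("cannot extract a label from shard item")


def make_validation_split(shards: dict, fraction: float, seed: int):
    """Split each site's shard into train and validation parts.

    Lesion-level and label-stratified within each site, using
    largest-remainder rounding so the per-site validation count equals
    ``round(fraction * n_site)``.  Sites too small to stratify (a single
    class, or fewer than two slides) fall back to an unstratified split
    with a warning.  The training part is never left empty.

    Returns ``(train_shards, val_shards)`` as dicts keyed like ``shards``.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_shards, val_shards = {}, {}
    for site in sorted(shards):
        items = list(shards[site])
        n = len(items)
        if n == 0:
            train_shards[site], val_shards[site] = [], []
            continue
        n_val = min(int(np.floor(fraction * n + 0.5)), n - 1)
        labels = np.asarray([_label_of(it) for it in items])
        classes = np.unique(labels)
        if len(classes) < 2 or n < 2:
            if len(classes) < 2:
                warnings.warn(f"site {site}: single class; unstratified split")
            order = rng.permutation(n)
            val_idx = set(order[:n_val].tolist())
        else:
            # largest-remainder allocation of n_val across classes
            quotas = {c: fraction * np.sum(labels == c) for c in classes}
            alloc = {c: int(math.floor(q)) for c, q in quotas.items()}
            short = n_val - sum(alloc.values())
            by_rem = sorted(
                classes, key=lambda c: (-(quotas[c] - alloc[c]), str(c))
            )
            for c in by_rem[:max(0, short)]:
                alloc[c] += 1
            while sum(alloc.values()) > n_val:
                c = by_rem[-1]
                if alloc[c] > 0:
                    alloc[c] -= 1
                by_rem = by_rem[-1:] + by_rem[:-1]
            val_idx = set()
            for c in classes:
                members = np.flatnonzero(labels == c)
                picked = rng.permutation(members)[: alloc[c]]
                val_idx.update(picked.tolist())
        train_shards[site] = [it for i, it in enumerate(items) if i not in val_idx]
        val_shards[site] = [it for i, it in enumerate(items) if i in val_idx]
    return train_shards, val_shards


@dataclass
class TuningResult:
    best_params: dict
    best_value: float
    trials: pd.DataFrame
    n_trials: int
    seed: int


def _transform(x, lo, hi, kind):
    return math.log(x) if kind == "log" else float(x)


def _untransform(z, lo, hi, kind):
    if kind == "log":
        x = math.exp(z)
    else:
        x = z
    x = min(max(x, lo), hi)
    if kind == "int":
        x = int(round(x))
    return x


def _kde_logpdf(x, centers, bw, span):
    """Log density of a Gaussian mixture over centers, 10% uniform floor."""
    z = (x - centers[:, None]) / bw
    kern = np.exp(-0.5 * z * z) / (bw * math.sqrt(2 * math.pi))
    dens = 0.9 * kern.mean(axis=0) + 0.1 / span
    return np.log(dens)


def tpe_search(objective, space: SearchSpace, n_trials: int, seed: int,
               n_startup: int = 5, gamma: float = 0.25,
               n_candidates: int = 24) -> TuningResult:
    """Sequential model-based maximisation of ``objective``.

    ``objective`` maps a parameter dict (keys from the search space) to a
    real score; higher is better.  Failing trials (exceptions) are logged
    and skipped.  Deterministic given ``seed``.
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    dims = space.dimensions()
    rng = np.random.default_rng(seed)
    observed = []  # (params, value)
    rows = []

    def random_params():
        params = {}
        for name, lo, hi, kind in dims:
            if kind == "log":
                z = rng.uniform(math.log(lo), math.log(hi))
            else:
                z = rng.uniform(lo, hi)
            params[name] = _untransform(z, lo, hi, kind)
        return params

    def tpe_params():
        vals = np.array([v for _, v in observed])
        order = np.argsort(-vals)
        n_good = max(1, math.ceil(gamma * len(observed)))
        good = [observed[i][0] for i in order[:n_good]]
        bad = [observed[i][0] for i in order[n_good:]]
        if not bad:
            return random_params()
        params = {}
        for name, lo, hi, kind in dims:
            zlo, zhi = (
                (math.log(lo), math.log(hi)) if kind == "log" else (lo, hi)
            )
            span = zhi - zlo
            g = np.array([_transform(p[name], lo, hi, kind) for p in good])
            b = np.array([_transform(p[name], lo, hi, kind) for p in bad])
            bw = max(g.std() * len(g) ** -0.2, span / 20.0)
            comp = rng.integers(0, len(g), size=n_candidates)
            cand = np.clip(g[comp] + rng.normal(0, bw, n_candidates), zlo, zhi)
            score = _kde_logpdf(cand, g, bw, span) - _kde_logpdf(cand, b, bw, span)
            params[name] = _untransform(float(cand[int(np.argmax(score))]), lo, hi, kind)
        return params

    for t in range(n_trials):
        params = random_params() if len(observed) < n_startup else tpe_params()
        try:
            value = float(objective(params))
            state = "complete"
        except Exception as exc:  # noqa: BLE001 - objective failures are data
            warnings.warn(f"trial {t} failed: {exc}")
            value, state = np.nan, "failed"
        rows.append({"trial": t, "value": value, "state": state, **params})
        if state == "complete":
            observed.append((params, value))

    if not observed:
        raise ValidationError("every trial failed")
    best_params, best_value = max(observed, key=lambda pv: pv[1])
    return TuningResult(
        best_params=dict(best_params), best_value=float(best_value),
        trials=pd.DataFrame(rows), n_trials=n_trials, seed=seed,
    )


def check_equal_trials(trial_counts: dict, override: bool = False) -> None:
    """Refuse cross-strategy comparisons with unequal tuning budgets.

    ``trial_counts`` maps strategy name to its number of TPE trials.
    Raises unless all counts are equal or ``override`` is set.
    """
    counts = set(trial_counts.values())
    if len(counts) > 1 and not override:
        raise ValidationError(
            f"strategies received unequal tuning budgets {trial_counts}; "
            "pass override=True to compare anyway"
        )
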