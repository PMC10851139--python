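"""End-to-end experiment orchestration.

``run_full_experiment`` reproduces the benchmark design on synthetic data:
generate six sites, preprocess and QC, split sites 1-5 into train/holdout
(site 6 is the external test set and never touches training or tuning),
train all eight models — federated, centralized on everything (Hfull),
five leave-one-site-out models (H1..H5) and the per-site ensemble — then
evaluate both test sets with a paired bootstrap and pairwise signed-rank
comparisons, and emit a table-shaped report plus ROC curve data.

Two built-in profiles size the experiment:

``full``
    Paper-scale geometry (896-px canvas, 224-px patches downscaled 1.84x,
    blur threshold 510, 50-patch inclusion rule, Table-1-sized sites).
``desk``
    The same design at 1/8 site sizes on a 128-px canvas with 32-px
    patches, sized to run on one CPU in a few minutes; the blur threshold
    (10.0) is calibrated once to the synthetic generator's
    Laplacian-variance scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .evaluation import (
    auroc,
    bootstrap_paired,
    confusion_metrics,
    pairwise_wilcoxon,
    prediction_table,
    roc_points,
)
from .federation import FederationConfig, run_federated_training
from .learners import ModelWeights, TrainConfig, predict_slide, save_weights
from .preprocessing import PreprocConfig, preprocess_dataset
from .strategies import ensemble_predict, train_centralized, train_ensemble, train_leave_one_out
from .synthetic import default_site_specs, generate_multisite_dataset, metadata_table
from .tuning import make_validation_split

__all__ = ["RunConfig", "run_full_experiment", "config_hash", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one full experiment.

    Round-trips losslessly through YAML; ``seed`` drives every random
    choice downstream (generation, splits, training, bootstrap).
    """

    seed: int = 0
    profile: str = "desk"
    canvas_px: int | None = None
    site_scale: float | None = None
    blur_fraction: float = 0.05
    external_site: int = 6
    holdout_fraction: float = 0.15
    n_boot: int = 1000
    alpha: float = 0.05
    preproc: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    federation: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.profile not in ("desk", "full"):
            raise ConfigurationError("profile must be 'desk' or 'full'")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        defaults = _PROFILES[self.profile]
        self.preproc = {**defaults["preproc"], **self.preproc}
        self.train = {**defaults["train"], **self.train}
        self.federation = {**defaults["federation"], **self.federation}
        if self.canvas_px is None:
            self.canvas_px = defaults["canvas_px"]
        if self.site_scale is None:
            self.site_scale = defaults["site_scale"]

    def preproc_config(self) -> PreprocConfig:
        return PreprocConfig(**self.preproc)

    def train_config(self, seed_offset: int = 0) -> TrainConfig:
        return TrainConfig(seed=self.seed + seed_offset, **self.train)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


_PROFILES = {
    "desk": {
        "preproc": {
            "edge_px": 32, "source_um_per_px": 0.25, "downscale": 1.0,
            "blur_threshold": 10.0, "min_patches": 4, "coverage_min": 0.5,
        },
        "train": {
            "lr_max": 0.05, "epochs": 4, "per_wsi_fraction": 0.5,
            "batch_size": 32, "backbone": "tiny_cnn", "momentum": 0.9,
        },
        "federation": {"sync_factor": 0.25, "n_rounds": 8, "weight_by": "slides"},
        "canvas_px": 128,
        "site_scale": 0.125,
    },
    "full": {
        "preproc": {
            "edge_px": 224, "source_um_per_px": 0.25, "downscale": 1.84,
            "blur_threshold": 510.0, "min_patches": 50, "coverage_min": 0.5,
        },
        "train": {
            "lr_max": 0.05, "epochs": 4, "per_wsi_fraction": 0.5,
            "batch_size": 32, "backbone": "tiny_cnn", "momentum": 0.9,
        },
        "federation": {"sync_factor": 0.25, "n_rounds": 8, "weight_by": "slides"},
        "canvas_px": 896,
        "site_scale": 1.0,
    },
}


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash identifying a config (carried by every artifact)."""
    canon = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _slide_prob(model, ps) -> float:
    if isinstance(model, list):
        return ensemble_predict(model, ps)
    return predict_slide(model, ps)


def _predict_table(model, model_id, pairs, test_set_id):
    ids = [ps.slide_id for ps, _ in pairs]
    labels = [lab for _, lab in pairs]
    probs = [_slide_prob(model, ps) for ps, _ in pairs]
    return prediction_table(ids, labels, probs, model_id, test_set_id)


def run_full_experiment(cfg: RunConfig, out_dir=None, write_weights: bool = False,
                        make_plots: bool = False) -> dict:
    """Run generation -> preprocessing -> training -> evaluation; return the report.

    The report is a plain JSON-able dict: per test set and model the mean
    and 95% percentile CI of AUROC/balanced accuracy/sensitivity/
    specificity over ``cfg.n_boot`` paired bootstrap replicates, confusion
    matrices at threshold 0.5, and the two pairwise signed-rank families
    (federated vs centralized/ensemble, and federated vs each
    leave-one-site-out model) with Bonferroni-adjusted thresholds.
    """
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # 1. generate + preprocess
    specs = default_site_specs(cfg.site_scale, cfg.blur_fraction)
    records = generate_multisite_dataset(specs, cfg.seed, canvas_px=cfg.canvas_px)
    included, _excluded, preproc_report = preprocess_dataset(records, cfg.preproc_config())

    # 2. split: sites != external form train/holdout; external never trains
    train_sites = sorted({r.site_id for r, _ in included} - {cfg.external_site})
    by_site = {
        site: [(ps, (r.label_int)) for r, ps in included if r.site_id == site]
        for site in train_sites
    }
    train_shards, holdout_shards = make_validation_split(
        by_site, cfg.holdout_fraction, seed=cfg.seed + 7
    )
    holdout = [pair for site in train_sites for pair in holdout_shards[site]]
    external = [
        (ps, r.label_int) for r, ps in included if r.site_id == cfg.external_site
    ]

    # 3. train the eight models
    shards_sorted = [train_shards[s] for s in train_sites]
    fed_cfg = FederationConfig(
        train_cfg=cfg.train_config(seed_offset=0), **cfg.federation
    )
    models: dict[str, object] = {}
    models["federated"] = run_federated_training(
        shards_sorted, fed_cfg,
        log_path=(out / "federated_rounds.jsonl") if out else None,
    )
    models["centralized"] = train_centralized(
        shards_sorted, cfg.train_config(seed_offset=101)
    )
    for k, site in enumerate(train_sites, start=1):
        models[f"H{k}"] = train_leave_one_out(
            train_shards, site, cfg.train_config(seed_offset=200 + k)
        )
    ens_cfgs = [
        cfg.train_config(seed_offset=1000 * (j + 1)) for j in range(len(train_sites))
    ]
    models["ensemble"] = train_ensemble(shards_sorted, ens_cfgs)

    # 4. evaluate on both test sets
    test_sets = {"holdout": holdout, "external": external}
    report = {
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "n_slides_generated": len(records),
        "preprocessing": preproc_report,
        "train_sites": train_sites,
        "n_train_slides": sum(len(s) for s in shards_sorted),
        "test_sets": {},
    }
    for set_id, pairs in test_sets.items():
        tables = {
            mid: _predict_table(m, mid, pairs, set_id) for mid, m in models.items()
        }
        boot = bootstrap_paired(tables, n_reps=cfg.n_boot, seed=cfg.seed + 31)
        loo_ids = [m for m in models if m.startswith("H")]
        fam_strategies = pairwise_wilcoxon(
            boot, pairs=[("federated", "centralized"), ("federated", "ensemble")],
            alpha=cfg.alpha,
        )
        fam_loo = pairwise_wilcoxon(
            boot, pairs=[("federated", h) for h in loo_ids], alpha=cfg.alpha,
        )
        block = {"n_slides": len(pairs), "models": {}, "pairwise": {
            "strategies": fam_strategies.to_dict(orient="records"),
            "federated_vs_leave_one_out": fam_loo.to_dict(orient="records"),
            "note": "signed-rank p-values are conditional on the bootstrap resampling",
        }}
        for mid in models:
            t = tables[mid]
            cm = confusion_metrics(t["true_label"], t["probability"])
            block["models"][mid] = {
                "metrics": {
                    metric: {
                        "mean": boot.means[mid][metric],
                        "ci_lo": boot.cis[mid][metric][0],
                        "ci_hi": boot.cis[mid][metric][1],
                    }
                    for metric in boot.replicates[mid]
                },
                "point_auroc": auroc(t["true_label"], t["probability"]),
                "confusion": cm.confusion.tolist(),
            }
        report["test_sets"][set_id] = block

        if out:
            pd.concat(tables.values()).to_csv(
                out / f"predictions_{set_id}.csv", index=False
            )
            for mid, t in tables.items():
                roc_points(t["true_label"], t["probability"]).to_csv(
                    out / f"roc_{set_id}_{mid}.csv", index=False
                )

    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        save_config(cfg, out / "config.yaml")
        splits = {}
        for site in train_sites:
            for ps, _ in holdout_shards[site]:
                splits[ps.slide_id] = "holdout"
            for ps, _ in train_shards[site]:
                splits[ps.slide_id] = "train"
        for ps, _ in external:
            splits[ps.slide_id] = "external"
        metadata_table(records, splits).to_csv(out / "metadata.csv", index=False)
        if write_weights:
            for mid, m in models.items():
                if isinstance(m, ModelWeights):
                    save_weights(m, out / f"weights_{mid}.npz")
        if make_plots:
            _plot_rocs(report, test_sets, models, out)
    return report


def _plot_rocs(report, test_sets, models, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for set_id in test_sets:
        fig, ax = plt.subplots(figsize=(5, 5))
        for mid in ("federated", "centralized", "ensemble"):
            csv = out / f"roc_{set_id}_{mid}.csv"
            pts = pd.read_csv(csv)
            auc = report["test_sets"][set_id]["models"][mid]["metrics"]["auroc"]["mean"]
            ax.plot(pts["fpr"], pts["tpr"], label=f"{mid} (AUROC {auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"{set_id} test set")
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        fig.savefig(out / f"roc_{set_id}.png", dpi=120)
        plt.close(fig)
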