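"""Slide-level evaluation: metrics, paired bootstrap, paired tests.

The evaluation unit is the slide (lesion).  Every model is summarised by a
prediction table of per-slide melanoma probabilities; AUROC is the primary
endpoint, balanced accuracy / sensitivity / specificity (at a probability
threshold of 0.5) are secondary.  Uncertainty comes from a paired
bootstrap: slides are resampled with replacement and *every* model is
scored on the same resampled index set per replicate, so replicate series
are directly comparable across models.  Model pairs are then compared with
two-sided Wilcoxon signed-rank tests on the paired replicate series, with
Bonferroni-adjusted significance thresholds; note that p-values obtained
this way are conditional on the resampling and flagged as such in reports.

Cohort-composition differences (age band, subtype, stage) are tested with
Pearson chi-square tests on contingency tables, "Unknown" rows excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "prediction_table",
    "auroc",
    "confusion_metrics",
    "percentile_ci",
    "BootstrapResult",
    "bootstrap_paired",
    "wilcoxon_signed_rank",
    "bonferroni",
    "chi_square_cohort_test",
    "pairwise_wilcoxon",
    "roc_points",
    "METRICS",
]

METRICS = ("auroc", "balanced_accuracy", "sensitivity", "specificity")


def prediction_table(slide_ids, labels, probabilities, model_id: str,
                     test_set_id: str = "") -> pd.DataFrame:
    """Assemble one model's per-slide prediction table."""
    probs = np.asarray(probabilities, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    return pd.DataFrame(
        {
            "slide_id": list(slide_ids),
            "true_label": np.asarray(labels, dtype=int),
            "probability": probs,
            "model_id": model_id,
            "test_set_id": test_set_id,
        }
    )


def _check_two_classes(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("both classes must be present")
    return y


def auroc(labels, scores) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney U statistic normalized by ``n_pos * n_neg``,
    with ties counted 1/2.  Requires both classes present.
    """
    y = _check_two_classes(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class ConfusionMetrics:
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]


def confusion_metrics(labels, scores, threshold: float = 0.5) -> ConfusionMetrics:
    """Threshold the probabilities and compute the secondary endpoints.

    Positive class is label 1 (melanoma); classification is
    ``probability >= threshold``.
    """
    y = _check_two_classes(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum((y == 1) & pred))
    fn = int(np.sum((y == 1) & ~pred))
    tn = int(np.sum((y == 0) & ~pred))
    fp = int(np.sum((y == 0) & pred))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ConfusionMetrics(
        balanced_accuracy=(sens + spec) / 2.0,
        sensitivity=sens,
        specificity=spec,
        confusion=np.array([[tn, fp], [fn, tp]]),
    )


def percentile_ci(samples, level: float = 0.95):
    """Nonparametric percentile interval with linear interpolation."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValidationError("samples must be non-empty")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(samples, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


@dataclass
class BootstrapResult:
    """Paired bootstrap replicates and summaries for a set of models.

    ``replicates[model][metric]`` is a length-``n_reps`` array; all models
    share the same resampled slide indices in every replicate, which is
    what makes downstream signed-rank comparisons paired.
    """

    n_reps: int
    seed: int
    model_ids: tuple
    replicates: dict  # model -> metric -> np.ndarray
    means: dict  # model -> metric -> float
    cis: dict  # model -> metric -> (lo, hi)
    n_slides: int = 0

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.model_ids:
            for metric in METRICS:
                lo, hi = self.cis[m][metric]
                rows.append(
                    {"model_id": m, "metric": metric,
                     "mean": self.means[m][metric], "ci_lo": lo, "ci_hi": hi}
                )
        return pd.DataFrame(rows)


def _metrics_matrix(scores: np.ndarray, labels: np.ndarray, threshold: float) -> dict:
    """All four metrics for a (n_reps, n) matrix of resampled scores/labels.

    AUROC via the rank form of the Mann-Whitney U (ties mid-ranked), which
    matches the single-sample :func:`auroc` exactly.
    """
    ranks = stats.rankdata(scores, axis=1)
    npos = labels.sum(axis=1)
    nneg = labels.shape[1] - npos
    au = (np.sum(ranks * labels, axis=1) - npos * (npos + 1) / 2) / (npos * nneg)
    pred = scores >= threshold
    tp = np.sum(labels & pred, axis=1)
    tn = np.sum((1 - labels) & ~pred, axis=1)
    sens = tp / npos
    spec = tn / nneg
    return {
        "auroc": au,
        "balanced_accuracy": (sens + spec) / 2.0,
        "sensitivity": sens,
        "specificity": spec,
    }


def bootstrap_paired(tables, n_reps: int = 1000, seed: int = 0,
                     level: float = 0.95, threshold: float = 0.5,
                     unit: str = "slide", max_redraws: int = 1000) -> BootstrapResult:
    """Paired bootstrap of all metrics for several models on one test set.

    Parameters
    ----------
    tables:
        Mapping of model id to prediction table (or a list of tables, keyed
        by their ``model_id`` column).  All tables must cover the identical
        slide set.
    unit:
        Resampling unit: ``"slide"`` (lesion level, default) or
        ``"patient"`` — with patient resampling all slides of a drawn
        patient enter together (tables then need a ``patient_id`` column).

    Replicates whose resample contains a single class are redrawn.
    """
    if not isinstance(tables, dict):
        tables = {str(t["model_id"].iloc[0]): t for t in tables}
    if not tables:
        raise ValidationError("no prediction tables given")
    model_ids = tuple(tables)
    ref = tables[model_ids[0]].sort_values("slide_id").reset_index(drop=True)
    slide_ids = ref["slide_id"].to_numpy()
    y = ref["true_label"].to_numpy(dtype=int)
    probs = {}
    for m in model_ids:
        t = tables[m].sort_values("slide_id").reset_index(drop=True)
        if not np.array_equal(t["slide_id"].to_numpy(), slide_ids):
            raise ValidationError(f"model {m} covers a different slide set")
        probs[m] = t["probability"].to_numpy(dtype=float)

    if unit == "patient":
        patients = ref["patient_id"].to_numpy()
        groups = [np.flatnonzero(patients == p) for p in pd.unique(patients)]
    elif unit == "slide":
        groups = None
    else:
        raise ValidationError("unit must be 'slide' or 'patient'")

    rng = np.random.default_rng(seed)
    n = len(slide_ids)
    if groups is None:
        # vectorized slide-level resampling; rows without both classes redrawn
        idx = np.empty((n_reps, n), dtype=np.int64)
        need = np.arange(n_reps)
        for _ in range(max_redraws):
            draw = rng.integers(0, n, size=(len(need), n))
            labs = y[draw]
            ok = (labs.any(axis=1)) & (~labs.all(axis=1))
            idx[need[ok]] = draw[ok]
            need = need[~ok]
            if need.size == 0:
                break
        else:
            raise ValidationError("could not draw two-class replicates")
        reps = {
            m: _metrics_matrix(probs[m][idx], y[idx], threshold)
            for m in model_ids
        }
    else:
        reps = {m: {metric: np.empty(n_reps) for metric in METRICS} for m in model_ids}
        for r in range(n_reps):
            for _ in range(max_redraws):
                g = rng.integers(0, len(groups), size=len(groups))
                row = np.concatenate([groups[i] for i in g])
                if len(np.unique(y[row])) == 2:
                    break
            else:
                raise ValidationError("could not draw a two-class replicate")
            for m in model_ids:
                vals = _metrics_matrix(
                    probs[m][row][None, :], y[row][None, :], threshold
                )
                for metric in METRICS:
                    reps[m][metric][r] = vals[metric][0]

    means = {m: {k: float(v.mean()) for k, v in reps[m].items()} for m in model_ids}
    cis = {m: {k: percentile_ci(v, level) for k, v in reps[m].items()} for m in model_ids}
    return BootstrapResult(
        n_reps=n_reps, seed=seed, model_ids=model_ids,
        replicates=reps, means=means, cis=cis, n_slides=n,
    )


def wilcoxon_signed_rank(a, b):
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; ties are mid-ranked.  The exact null
    distribution is used for <= 25 non-zero pairs without rank ties,
    otherwise the normal approximation with continuity correction (the
    exact distribution is undefined under mid-ranked ties).  Returns
    ``(statistic, p)``; all-zero differences give ``p = 1.0`` with a
    warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("a and b must have the same length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1.0")
        return 0.0, 1.0
    ranks_tied = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not ranks_tied) else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-comparison significance level ``alpha / m``."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m


def chi_square_cohort_test(contingency):
    """Pearson chi-square homogeneity test on a category x group table.

    Accepts a 2-D array or a DataFrame (categories as rows); rows indexed
    "Unknown" are excluded, then rows/columns with a zero marginal are
    dropped with a warning.  No continuity correction; ``df = (r-1)(c-1)``.
    Returns ``(statistic, df, p)``.
    """
    if isinstance(contingency, pd.DataFrame):
        table = contingency.loc[
            [i for i in contingency.index if str(i).lower() != "unknown"]
        ].to_numpy(dtype=float)
    else:
        table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("need a table with >= 2 rows and >= 2 columns")
    row_ok = table.sum(axis=1) > 0
    col_ok = table.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-marginal categories from contingency table")
        table = table[row_ok][:, col_ok]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise UndefinedMetricError("table degenerate after dropping empty categories")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def pairwise_wilcoxon(result: BootstrapResult, pairs=None, metric: str = "auroc",
                      alpha: float = 0.05) -> pd.DataFrame:
    """Signed-rank comparisons between models on paired bootstrap replicates.

    ``pairs`` defaults to all unordered model pairs; the Bonferroni
    threshold uses the number of comparisons actually made.  The returned
    frame carries one row per pair (statistic, p, adjusted threshold,
    significance flag).
    """
    if pairs is None:
        ids = result.model_ids
        pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    m = len(pairs)
    thr = bonferroni(alpha, m)
    rows = []
    for a, b in pairs:
        stat, p = wilcoxon_signed_rank(
            result.replicates[a][metric], result.replicates[b][metric]
        )
        rows.append(
            {"model_a": a, "model_b": b, "metric": metric, "statistic": stat,
             "p_value": p, "alpha_adjusted": thr, "significant": p < thr,
             "mean_a": result.means[a][metric], "mean_b": result.means[b][metric]}
        )
    return pd.DataFrame(rows)


def roc_points(labels, scores) -> pd.DataFrame:
    """ROC curve support points (fpr, tpr, threshold) for plotting."""
    y = _check_two_classes(labels)
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
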