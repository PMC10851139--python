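"""Metrics, paired bootstrap and paired-test behaviour against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedslide.errors import UndefinedMetricError, ValidationError
from fedslide.evaluation import (
    bonferroni,
    bootstrap_paired,
    chi_square_cohort_test,
    confusion_metrics,
    pairwise_wilcoxon,
    percentile_ci,
    prediction_table,
    wilcoxon_signed_rank,
)
from fedslide.evaluation import auroc


def brute_force_auroc(labels, scores):
    """All-pairs Mann-Whitney count with ties worth 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


def enumerate_wilcoxon_p(d):
    """Exact two-sided signed-rank p by full 2^n sign enumeration."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_pos = ranks[d > 0].sum()
    total = ranks.sum()
    w_min = min(w_pos, total - w_pos)
    stats = []
    for signs in range(2**n):
        mask = np.array([(signs >> i) & 1 for i in range(n)], dtype=bool)
        stats.append(ranks[mask].sum())
    stats = np.asarray(stats)
    # two-sided: double the smaller tail (symmetric null), capped at 1
    return float(min(1.0, 2.0 * np.mean(stats <= w_min)))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_hand_enumerated_example(self):
        # pos scores .9, .7 vs neg .8, .6: wins 2 + 1 of 4 pairs
        assert auroc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1, 1, 1], [0.1, 0.5, 0.9])

    def test_agrees_with_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 31)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            assert auroc(labels, scores) == pytest.approx(
                brute_force_auroc(labels, scores), abs=1e-12
            )


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        cm = confusion_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert (cm.sensitivity, cm.specificity, cm.balanced_accuracy) == (1, 1, 1)

    def test_all_negative_predictor(self):
        cm = confusion_metrics([0, 0, 1, 1], [0.1, 0.2, 0.3, 0.4])
        assert cm.sensitivity == 0.0
        assert cm.specificity == 1.0
        assert cm.balanced_accuracy == 0.5

    def test_hand_counted_mixed_case(self):
        # 2 TP, 1 FN, 3 TN, 1 FP
        labels = [1, 1, 1, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.2, 0.1, 0.2, 0.3, 0.7]
        cm = confusion_metrics(labels, scores)
        assert cm.sensitivity == pytest.approx(2 / 3)
        assert cm.specificity == pytest.approx(3 / 4)
        assert cm.balanced_accuracy == pytest.approx(17 / 24)
        np.testing.assert_array_equal(cm.confusion, [[3, 1], [1, 2]])

    def test_threshold_semantics_are_geq(self):
        cm = confusion_metrics([0, 1], [0.4, 0.5], threshold=0.5)
        assert cm.sensitivity == 1.0 and cm.specificity == 1.0


class TestPercentileCI:
    def test_constant_samples_collapse(self):
        assert percentile_ci([3.3] * 50) == (3.3, 3.3)

    def test_1_to_1000_linear_interpolation(self):
        lo, hi = percentile_ci(np.arange(1, 1001), 0.95)
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40),
           st.floats(0.5, 0.99))
    def test_interval_brackets_the_median(self, samples, level):
        lo, hi = percentile_ci(samples, level)
        med = float(np.median(samples))
        assert lo <= med <= hi


def _tables(labels, prob_by_model, ids=None):
    ids = ids or [f"s{i}" for i in range(len(labels))]
    return {
        m: prediction_table(ids, labels, p, m, "t") for m, p in prob_by_model.items()
    }


class TestBootstrapPaired:
    def test_perfect_models_collapse_ci(self):
        labels = [0, 0, 0, 1, 1, 1]
        tables = _tables(labels, {"a": [0.1, 0.2, 0.1, 0.9, 0.8, 0.9],
                                  "b": [0.2, 0.1, 0.3, 0.7, 0.8, 0.9]})
        res = bootstrap_paired(tables, n_reps=100, seed=1)
        assert (res.replicates["a"]["auroc"] == 1.0).all()
        assert res.cis["a"]["auroc"] == (1.0, 1.0)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        probs = {m: rng.random(30) for m in ("a", "b")}
        r1 = bootstrap_paired(_tables(labels, probs), n_reps=50, seed=9)
        r2 = bootstrap_paired(_tables(labels, probs), n_reps=50, seed=9)
        for m in ("a", "b"):
            np.testing.assert_array_equal(
                r1.replicates[m]["auroc"], r2.replicates[m]["auroc"]
            )

    def test_pairing_raises_cross_model_correlation(self):
        # two noisy views of one signal: paired replicate series must be
        # more correlated than independently resampled series
        rng = np.random.default_rng(2)
        n = 60
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        base = np.clip(labels * 0.4 + rng.normal(0.3, 0.2, n), 0, 1)
        pa = np.clip(base + rng.normal(0, 0.05, n), 0, 1)
        pb = np.clip(base + rng.normal(0, 0.05, n), 0, 1)
        paired = bootstrap_paired(_tables(labels, {"a": pa, "b": pb}),
                                  n_reps=300, seed=0)
        rho_paired = np.corrcoef(paired.replicates["a"]["auroc"],
                                 paired.replicates["b"]["auroc"])[0, 1]
        ra = bootstrap_paired(_tables(labels, {"a": pa}), n_reps=300, seed=1)
        rb = bootstrap_paired(_tables(labels, {"b": pb}), n_reps=300, seed=2)
        rho_unpaired = np.corrcoef(ra.replicates["a"]["auroc"],
                                   rb.replicates["b"]["auroc"])[0, 1]
        assert rho_paired > rho_unpaired

    def test_mismatched_slide_sets_rejected(self):
        t1 = prediction_table(["a", "b"], [0, 1], [0.1, 0.9], "m1")
        t2 = prediction_table(["a", "c"], [0, 1], [0.1, 0.9], "m2")
        with pytest.raises(ValidationError):
            bootstrap_paired({"m1": t1, "m2": t2}, n_reps=10, seed=0)

    def test_ci_contains_point_estimate_in_most_runs(self):
        # percentile CI of AUROC replicates should cover the full-sample
        # point estimate in >= 95% of seeded synthetic runs
        rng = np.random.default_rng(7)
        hits = 0
        runs = 100
        for s in range(runs):
            n = 40
            labels = np.r_[np.zeros(20, int), np.ones(20, int)]
            probs = np.clip(labels * 0.3 + rng.normal(0.35, 0.25, n), 0, 1)
            point = auroc(labels, probs)
            res = bootstrap_paired(_tables(labels, {"m": probs}),
                                   n_reps=200, seed=s)
            lo, hi = res.cis["m"]["auroc"]
            hits += lo <= point <= hi
        assert hits >= 95


class TestWilcoxon:
    def test_equal_series_give_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            stat, p = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_six_uniform_positive_differences(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a - np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(2 / 64)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(15), rng.random(15)
        assert wilcoxon_signed_rank(a, b)[1] == pytest.approx(
            wilcoxon_signed_rank(b, a)[1]
        )

    def test_exact_p_matches_full_enumeration(self):
        rng = np.random.default_rng(1)
        for n in (5, 7, 9, 11, 12):
            for _ in range(3):
                d = rng.normal(0.2, 1.0, n)
                d = d[np.abs(d) > 1e-9]
                if len(np.unique(np.abs(d))) < len(d) or len(d) == 0:
                    continue
                _, p = wilcoxon_signed_rank(d, np.zeros_like(d))
                assert p == pytest.approx(enumerate_wilcoxon_p(d), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected",
                             [(0.05, 2, 0.025), (0.05, 5, 0.01), (0.05, 1, 0.05)])
    def test_adjusted_levels(self, alpha, m, expected):
        assert bonferroni(alpha, m) == pytest.approx(expected)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni(0.05, 0)


class TestChiSquare:
    def test_homogeneous_table(self):
        stat, df, p = chi_square_cohort_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_pearson_formula(self):
        # expected counts all 15; chi2 = 4 * 25/15 = 20/3
        stat, df, _ = chi_square_cohort_test([[20, 10], [10, 20]])
        assert stat == pytest.approx(20 / 3)
        assert df == 1

    def test_degrees_of_freedom_4x2(self):
        table = np.array([[5, 8], [7, 3], [9, 9], [4, 6]])
        _, df, _ = chi_square_cohort_test(table)
        assert df == 3

    def test_unknown_rows_excluded(self):
        import pandas as pd

        with_unknown = pd.DataFrame(
            [[20, 10], [10, 20], [3, 0]],
            index=["a", "b", "Unknown"], columns=["g1", "g2"],
        )
        stat, df, _ = chi_square_cohort_test(with_unknown)
        assert stat == pytest.approx(20 / 3)
        assert df == 1

    def test_zero_marginal_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-marginal"):
            _, df, _ = chi_square_cohort_test([[10, 5], [0, 0], [5, 10]])
        assert df == 1


class TestPairwise:
    def test_frame_covers_all_pairs_with_adjusted_threshold(self):
        rng = np.random.default_rng(0)
        labels = np.r_[np.zeros(15, int), np.ones(15, int)]
        probs = {m: np.clip(labels * 0.4 + rng.normal(0.3, 0.2, 30), 0, 1)
                 for m in ("x", "y", "z")}
        res = bootstrap_paired(_tables(labels, probs), n_reps=60, seed=3)
        frame = pairwise_wilcoxon(res, alpha=0.05)
        assert len(frame) == 3
        np.testing.assert_allclose(frame["alpha_adjusted"], 0.05 / 3)
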