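"""Backbones, the 1-cycle schedule, local training and slide inference."""

import numpy as np
import pytest

from fedslide.errors import (
    ConfigurationError,
    UndefinedPredictionError,
    ValidationError,
)
from fedslide.learners import (
    PatchCNNSlideClassifier,
    TrainConfig,
    build_backbone,
    load_weights,
    one_cycle_lr,
    predict_patch_probs,
    predict_slide,
    sample_epoch_patches,
    save_weights,
    train_local,
)

from conftest import make_patchset, random_patches


class TestBuildBackbone:
    def test_same_seed_same_arrays(self):
        a = build_backbone("tiny_cnn", 5)
        b = build_backbone("tiny_cnn", 5)
        assert a.allclose(b, rtol=0, atol=0)

    def test_different_seeds_differ(self):
        a = build_backbone("tiny_cnn", 5)
        b = build_backbone("tiny_cnn", 6)
        assert not a.allclose(b)

    def test_tiny_cnn_parameter_budget(self):
        assert build_backbone("tiny_cnn", 0).n_params() < 100_000

    def test_resnet18_two_class_head_and_determinism(self):
        w = build_backbone("resnet18", 1)
        head = [k for k in w.entries if k.endswith("weight")][-1]
        assert w.entries[head].shape == (2, 512)
        assert w.n_params() > 11_000_000
        assert w.allclose(build_backbone("resnet18", 1), rtol=0, atol=0)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ConfigurationError):
            build_backbone("vit_large", 0)


class TestOneCycle:
    def test_peak_at_half_and_endpoints(self):
        total, lr_max = 100, 0.8
        assert one_cycle_lr(total // 2, total, lr_max) == pytest.approx(lr_max)
        assert one_cycle_lr(0, total, lr_max) == pytest.approx(lr_max / 25)
        assert one_cycle_lr(total - 1, total, lr_max) == pytest.approx(
            lr_max / 2500
        )

    def test_monotone_ramp_then_anneal_full_enumeration(self):
        total = 100
        lrs = [one_cycle_lr(s, total, 0.1) for s in range(total)]
        peak = int(np.argmax(lrs))
        assert peak == total // 2
        assert all(b >= a for a, b in zip(lrs[: peak + 1], lrs[1 : peak + 1]))
        assert all(b <= a for a, b in zip(lrs[peak:], lrs[peak + 1 :]))

    @pytest.mark.parametrize("step", [-1, 100, 1000])
    def test_out_of_range_step_rejected(self, step):
        with pytest.raises(ValidationError):
            one_cycle_lr(step, 100, 0.1)


class TestSampleEpochPatches:
    def _ps(self, n_kept, n_total=None):
        n_total = n_total or n_kept
        return make_patchset(
            np.zeros((n_total, 8, 8, 3)),
            kept=[True] * n_kept + [False] * (n_total - n_kept),
        )

    def test_full_fraction_returns_all_kept_shuffled(self):
        ps = self._ps(10, 12)
        idx = sample_epoch_patches(ps, 1.0, np.random.default_rng(0))
        assert sorted(idx) == list(range(10))

    @pytest.mark.parametrize("fraction,expected", [(0.5, 5), (0.01, 1)])
    def test_ceil_count(self, fraction, expected):
        idx = sample_epoch_patches(self._ps(10), fraction, np.random.default_rng(0))
        assert len(idx) == expected
        assert len(set(idx.tolist())) == expected  # without replacement

    def test_no_kept_patches_rejected(self):
        with pytest.raises(ValidationError):
            sample_epoch_patches(self._ps(0, 3), 0.5, np.random.default_rng(0))


def _toy_shard(rng, n_slides=8, edge=16):
    """Linearly separable two-colour toy: class 1 bright red, class 0 dark blue."""
    shard = []
    for i in range(n_slides):
        label = i % 2
        base = np.array([200, 40, 30] if label else [30, 40, 170], dtype=np.uint8)
        patches = np.clip(
            base[None, None, None, :].astype(int)
            + rng.integers(-20, 21, size=(6, edge, edge, 3)),
            0, 255,
        ).astype(np.uint8)
        shard.append((make_patchset(patches, slide_id=f"t{i}"), label))
    return shard


class TestTrainLocal:
    def test_zero_steps_is_identity(self):
        rng = np.random.default_rng(0)
        shard = _toy_shard(rng)
        w = build_backbone("tiny_cnn", 0)
        out = train_local(w, shard, TrainConfig(seed=1), n_steps=0)
        assert out.allclose(w, rtol=0, atol=0)

    def test_training_is_bitwise_deterministic(self):
        rng = np.random.default_rng(0)
        shard = _toy_shard(rng)
        cfg = TrainConfig(seed=3, epochs=2, batch_size=8)
        w0 = build_backbone("tiny_cnn", 0)
        a = train_local(w0, shard, cfg)
        b = train_local(w0, shard, cfg)
        for k in a.entries:
            np.testing.assert_array_equal(a.entries[k], b.entries[k])

    def test_loss_decreases_on_separable_toy(self):
        rng = np.random.default_rng(0)
        shard = _toy_shard(rng)
        cfg = TrainConfig(seed=3, epochs=5, batch_size=8, lr_max=0.05)
        from fedslide.learners import LocalTrainer

        w0 = build_backbone("tiny_cnn", 0)
        tr_first = LocalTrainer(shard, cfg)
        tr_first.run(w0, tr_first.steps_per_epoch)
        initial_loss = tr_first.last_epoch_loss

        tr = LocalTrainer(shard, cfg)
        tr.run(w0)
        assert tr.last_epoch_loss < initial_loss

    def test_backbone_mismatch_rejected(self):
        from fedslide.errors import ContractError

        rng = np.random.default_rng(0)
        shard = _toy_shard(rng)
        w = build_backbone("tiny_cnn", 0)
        with pytest.raises(ContractError):
            train_local(w, shard, TrainConfig(seed=1, backbone="resnet18"), n_steps=1)

    def test_resnet18_single_step_updates_weights(self):
        rng = np.random.default_rng(0)
        shard = _toy_shard(rng, n_slides=2, edge=32)
        w = build_backbone("resnet18", 0)
        cfg = TrainConfig(seed=1, backbone="resnet18", batch_size=4)
        out = train_local(w, shard, cfg, n_steps=1)
        assert not out.allclose(w)


class TestPredictSlide:
    def test_slide_probability_is_mean_of_patch_probabilities(self):
        rng = np.random.default_rng(0)
        w = build_backbone("tiny_cnn", 0)
        ps = make_patchset(random_patches(rng, 7, 16))
        per_patch = predict_patch_probs(w, ps.patches)
        assert predict_slide(w, ps) == pytest.approx(per_patch.mean(), abs=1e-6)
        assert 0.0 <= predict_slide(w, ps) <= 1.0

    def test_single_patch_slide(self):
        rng = np.random.default_rng(1)
        w = build_backbone("tiny_cnn", 0)
        ps = make_patchset(random_patches(rng, 1, 16))
        assert predict_slide(w, ps) == pytest.approx(
            predict_patch_probs(w, ps.patches)[0], abs=1e-6
        )

    def test_patch_order_invariance(self):
        rng = np.random.default_rng(2)
        w = build_backbone("tiny_cnn", 0)
        patches = random_patches(rng, 6, 16)
        a = predict_slide(w, make_patchset(patches))
        b = predict_slide(w, make_patchset(patches[::-1]))
        assert a == pytest.approx(b, abs=1e-6)

    def test_only_kept_patches_enter_the_mean(self):
        rng = np.random.default_rng(3)
        w = build_backbone("tiny_cnn", 0)
        patches = random_patches(rng, 4, 16)
        kept = [True, True, False, False]
        full = predict_patch_probs(w, patches)
        ps = make_patchset(patches, kept=kept)
        assert predict_slide(w, ps) == pytest.approx(full[:2].mean(), abs=1e-6)

    def test_zero_kept_patches_rejected(self):
        rng = np.random.default_rng(4)
        w = build_backbone("tiny_cnn", 0)
        ps = make_patchset(random_patches(rng, 3, 16), kept=[False] * 3)
        with pytest.raises(UndefinedPredictionError):
            predict_slide(w, ps)


class TestWeightsRoundTrip:
    def test_save_load_identity(self, tmp_path):
        w = build_backbone("tiny_cnn", 9)
        save_weights(w, tmp_path / "w.npz")
        back = load_weights(tmp_path / "w.npz")
        assert back.allclose(w, rtol=0, atol=0)
        assert back.meta["backbone"] == "tiny_cnn"


class TestEstimator:
    def test_fit_predict_separates_toy_classes(self):
        rng = np.random.default_rng(0)
        shard = _toy_shard(rng, n_slides=12)
        X = [ps for ps, _ in shard]
        y = np.array([lab for _, lab in shard])
        clf = PatchCNNSlideClassifier(epochs=5, batch_size=8, seed=1).fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (12, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        from fedslide.evaluation import auroc

        assert auroc(y, proba[:, 1]) > 0.9

    def test_sklearn_param_interface(self):
        clf = PatchCNNSlideClassifier(lr_max=0.01)
        assert clf.get_params()["lr_max"] == 0.01
        clf.set_params(epochs=7)
        assert clf.epochs == 7
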