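"""Folds, schedule, augmentation policy, pretext training and fine-tuning."""

import numpy as np
import pytest

from fractalseg import nn
from fractalseg.training import (AugmentationPolicy, FoldSplit, ModelSpec,
                                 ScheduleConfig, augment_pair, finetune,
                                 make_folds, predict_mask, pretext_train,
                                 select_best_epoch, warmup_lr)
from fractalseg.pipeline import evaluate_model_on_cases

NO_AUG = AugmentationPolicy(p_hflip=0, p_shift_scale=0, p_gauss_noise=0,
                            p_perspective=0, p_contrast_group=0,
                            p_sharpen_group=0, p_color_group=0)


class TestMakeFolds:
    def test_fourfold_104_cases(self):
        ids = [f"p{i:03d}" for i in range(104)]
        folds = make_folds(ids, k=4, sizes=(63, 15, 26), seed=0)
        assert len(folds) == 4
        tests = [set(f.test_ids) for f in folds]
        assert all(len(t) == 26 for t in tests)
        assert set().union(*tests) == set(ids)  # exhaustive
        for i in range(4):
            for j in range(i + 1, 4):
                assert not tests[i] & tests[j]  # disjoint
        for f in folds:
            assert (len(f.train_ids), len(f.val_ids), len(f.test_ids)) == (63, 15, 26)
            assert set(f.train_ids) | set(f.val_ids) | set(f.test_ids) == set(ids)

    def test_small_cohort(self):
        folds = make_folds([f"c{i}" for i in range(8)], k=4, sizes=(5, 1, 2), seed=1)
        assert all(len(f.test_ids) == 2 for f in folds)

    def test_deterministic(self):
        ids = [f"p{i}" for i in range(16)]
        f1 = make_folds(ids, k=4, sizes=(10, 2, 4), seed=5)
        f2 = make_folds(ids, k=4, sizes=(10, 2, 4), seed=5)
        assert f1 == f2

    def test_non_divisible_cohort_rejected(self):
        with pytest.raises(ValueError, match="remainder"):
            make_folds([f"c{i}" for i in range(10)], k=4, sizes=(5, 2, 3), seed=0)


class TestWarmupLR:
    def test_printed_endpoints_and_linear_interior(self):
        sched = ScheduleConfig()
        expected = [2e-5, 4e-5, 6e-5, 8e-5] + [1e-4] * 46
        got = [warmup_lr(e, sched) for e in range(1, 51)]
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_epoch_zero_rejected(self):
        with pytest.raises(ValueError):
            warmup_lr(0, ScheduleConfig())

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            ScheduleConfig(lr_start=1e-3, lr_target=1e-4)


class TestAugmentPair:
    def _pair(self, rng):
        img = rng.random((64, 64))
        msk = np.zeros((64, 64), dtype=np.uint8)
        msk[20:40, 25:45] = 1
        return img, msk

    def test_all_disabled_is_identity(self, rng):
        img, msk = self._pair(rng)
        out_i, out_m = augment_pair(img, msk, NO_AUG, seed=0)
        np.testing.assert_array_equal(out_i, img)
        np.testing.assert_array_equal(out_m, msk)

    def test_mirror_reverses_both(self, rng):
        img, msk = self._pair(rng)
        policy = AugmentationPolicy(p_hflip=1.0, p_shift_scale=0, p_gauss_noise=0,
                                    p_perspective=0, p_contrast_group=0,
                                    p_sharpen_group=0, p_color_group=0)
        out_i, out_m = augment_pair(img, msk, policy, seed=0)
        np.testing.assert_array_equal(out_i, img[:, ::-1])
        np.testing.assert_array_equal(out_m, msk[:, ::-1])

    def test_audit_mask_binary_and_geometric_only(self, rng):
        """Over 200 seeded draws the mask stays binary, and with all geometric
        transforms disabled the mask never changes."""
        img, msk = self._pair(rng)
        full = AugmentationPolicy()
        photometric_only = AugmentationPolicy(p_hflip=0, p_shift_scale=0,
                                              p_perspective=0)
        for seed in range(200):
            _, m_full = augment_pair(img, msk, full, seed=seed)
            assert set(np.unique(m_full)) <= {0, 1}
            _, m_photo = augment_pair(img, msk, photometric_only, seed=seed)
            np.testing.assert_array_equal(m_photo, msk)

    def test_seeded_determinism(self, rng):
        img, msk = self._pair(rng)
        a = augment_pair(img, msk, AugmentationPolicy(), seed=3)
        b = augment_pair(img, msk, AugmentationPolicy(), seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            augment_pair(np.zeros((64, 64)), np.zeros((32, 32), dtype=np.uint8),
                         AugmentationPolicy(), seed=0)


class TestSelectBestEpoch:
    @pytest.mark.parametrize("losses,expected", [
        ([3.0, 2.0, 4.0], 2),
        ([2.0, 2.0], 1),          # tie -> earliest
        ([5.0, 4.0, 3.0, 2.0], 4),  # strictly decreasing -> last
    ])
    def test_rule(self, losses, expected):
        assert select_best_epoch(losses) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_epoch([])


class TestPretextTrain:
    def test_separable_toy_reaches_high_accuracy(self, toy_db):
        """Two well-separated fractal categories x 40 instances, 20 epochs:
        held-out pretext accuracy exceeds 0.9 and the loss trace decreases."""
        _, out, manifest = toy_db
        state, log = pretext_train(manifest, out, ModelSpec(), epochs=20, seed=0,
                                   val_fraction=0.2)
        assert log["val_accuracy"].iloc[-1] > 0.9
        assert log["train_loss"].iloc[-1] < log["train_loss"].iloc[0]
        assert set(state) == {f"enc{i}.{p}" for i in range(4) for p in "Wb"}

    def test_zero_epochs_returns_initialization(self, toy_db):
        _, out, manifest = toy_db
        state, log = pretext_train(manifest, out, ModelSpec(), epochs=0, seed=5)
        ref = nn.FractalClassifier(2, seed=5).encoder.params()
        for k in state:
            np.testing.assert_array_equal(state[k], ref[k])
        assert len(log) == 0

    def test_single_category_rejected(self, toy_db):
        _, out, manifest = toy_db
        single = manifest[manifest["category_id"] == 0]
        with pytest.raises(ValueError):
            pretext_train(single, out, ModelSpec(), epochs=1, seed=0)


def _fold_from(rois, n_train, n_val, n_test):
    ids = sorted(rois)
    return FoldSplit(0, tuple(ids[:n_train]),
                     tuple(ids[n_train:n_train + n_val]),
                     tuple(ids[n_train + n_val:n_train + n_val + n_test]))


class TestFinetune:
    def test_lr_trace_matches_schedule(self, small_rois):
        sched = ScheduleConfig(max_epochs=6, warmup_end_epoch=5)
        fold = _fold_from(small_rois, 2, 1, 1)
        res = finetune(ModelSpec(), fold, small_rois, sched=sched, policy=None,
                       seed=0)
        expected = [warmup_lr(e, sched) for e in range(1, 7)]
        assert list(res.lr_trace) == expected
        assert len(res.val_losses) == 6
        assert res.best_epoch == select_best_epoch(list(res.val_losses))

    def test_deterministic_val_loss_trace(self, small_rois):
        sched = ScheduleConfig(max_epochs=2, warmup_end_epoch=2)
        fold = _fold_from(small_rois, 2, 1, 1)
        r1 = finetune(ModelSpec(), fold, small_rois, sched=sched, seed=3)
        r2 = finetune(ModelSpec(), fold, small_rois, sched=sched, seed=3)
        assert r1.val_losses == r2.val_losses

    def test_overfits_single_case(self, small_rois):
        """Capacity check: training and validating on one case with no
        augmentation at an aggressive rate overfits it to vDSC > 0.9."""
        cid, other = sorted(small_rois)[:2]
        fold = FoldSplit(0, (cid,), (other,), ())
        sched = ScheduleConfig(lr_start=2e-4, lr_target=1e-3, warmup_end_epoch=5,
                               max_epochs=200, batch_size=8)
        res = finetune(ModelSpec(), fold, small_rois, sched=sched, policy=None,
                       seed=0)
        cm = evaluate_model_on_cases(res.model, small_rois, [cid], "overfit")[0]
        assert cm.vdsc > 0.9

    def test_missing_roi_data_rejected(self, small_rois):
        fold = FoldSplit(0, ("nope",), (sorted(small_rois)[0],), ())
        with pytest.raises(KeyError):
            finetune(ModelSpec(), fold, small_rois)


class TestPredictMask:
    def test_output_shape_and_binarity(self, small_rois):
        model = nn.SegNet(seed=0)
        img = next(iter(small_rois.values())).pairs[0].image
        mask = predict_mask(model, img)
        assert mask.shape == (64, 64)
        assert set(np.unique(mask)) <= {0, 1}

    def test_resize_round_trip_path(self, small_rois):
        """input_side=224 path: upsample in, downsample out, still 64x64."""
        model = nn.SegNet(seed=0)
        img = next(iter(small_rois.values())).pairs[0].image
        mask = predict_mask(model, img, input_side=224)
        assert mask.shape == (64, 64)

    def test_threshold_equals_two_class_argmax(self, rng):
        """For a two-class head with logits (0, z), sigmoid(z) > 0.5 picks the
        same class as argmax."""
        z = rng.normal(0, 3, size=1000)
        two_class = np.stack([np.zeros_like(z), z], axis=1)
        assert ((nn.sigmoid(z) > 0.5) == two_class.argmax(axis=1).astype(bool)).all()


class TestFoldSplitInvariants:
    def test_overlapping_subsets_rejected(self):
        with pytest.raises(ValueError):
            FoldSplit(0, ("a", "b"), ("b",), ("c",))

    def test_conservation(self):
        ids = [f"c{i}" for i in range(12)]
        for f in make_folds(ids, k=4, sizes=(7, 2, 3), seed=2):
            assert len(f.train_ids) + len(f.val_ids) + len(f.test_ids) == 12
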