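import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scapseg import training as tr
from scapseg.imaging import GridMismatchError, Mask, ProbMap, Volume
from scapseg.training import (EmptyEnsembleError, TrainConfig, TrainingError,
                              TrainedModelRecord, build_ensemble,
                              dice_coefficient, ensemble_predict, kfold_split,
                              neg_log_dice_loss, train)
from scapseg.vnet import VNetConfig, build_model


def _mask(arr):
    return Mask(np.asarray(arr, np.uint8))


class TestDice:
    def test_identical_nonempty_masks(self):
        m = _mask(np.ones((3, 3, 3)))
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((2, 2, 2)), np.zeros((2, 2, 2))
        a[0][0, 0, 0] = 1
        a[1][1, 1, 1] = 1
        assert dice_coefficient(_mask(a[0]), _mask(a[1])) == 0.0

    def test_half_overlap_is_half(self):
        a = np.zeros((2, 2, 2))
        b = np.zeros((2, 2, 2))
        a.ravel()[:4] = 1
        b.ravel()[2:6] = 1
        assert dice_coefficient(_mask(a), _mask(b)) == 0.5

    def test_both_empty_is_one(self):
        z = _mask(np.zeros((2, 2, 2)))
        assert dice_coefficient(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(GridMismatchError):
            dice_coefficient(np.zeros((2, 2)), np.zeros((3, 3)))


class TestNegLogDiceLoss:
    def test_perfect_prediction_zero_loss(self):
        y = np.zeros((3, 3, 3))
        y[1] = 1
        assert neg_log_dice_loss(y, y, smooth=0.0) == 0.0

    def test_half_dice_is_log10_two(self):
        a = np.zeros(8)
        b = np.zeros(8)
        a[:4] = 1
        b[2:6] = 1
        assert neg_log_dice_loss(a, b, smooth=0.0) == pytest.approx(
            math.log10(2.0))

    def test_smoothing_keeps_loss_finite(self):
        p = np.zeros((3, 3, 3))
        y = np.ones((3, 3, 3))
        loss = neg_log_dice_loss(p, y, smooth=1e-5)
        assert np.isfinite(loss) and loss > 3.0

    def test_both_empty_smooth_zero_rejected(self):
        z = np.zeros((2, 2, 2))
        with pytest.raises(ValueError):
            neg_log_dice_loss(z, z, smooth=0.0)

    def test_loss_equals_neg_log_dice(self, rng):
        for _ in range(20):
            p = rng.random((4, 4, 4))
            y = (rng.random((4, 4, 4)) < 0.4).astype(float)
            d = dice_coefficient(p, y)
            assert neg_log_dice_loss(p, y, smooth=0.0) == pytest.approx(
                -math.log10(d))


class TestKFold:
    def test_55_subjects_5_folds(self):
        split = kfold_split(list(range(55)), 5)
        sizes = [len(v) for _, v in split.folds]
        assert sizes == [11] * 5
        assert split.folds[0][1] == list(range(11))

    def test_4_subjects_2_folds(self):
        split = kfold_split([0, 1, 2, 3], 2)
        assert split.folds[0][1] == [0, 1]
        assert split.folds[1][1] == [2, 3]

    def test_remainder_rule_larger_folds_first(self):
        split = kfold_split(list(range(7)), 3)
        assert [len(v) for _, v in split.folds] == [3, 2, 2]

    @pytest.mark.parametrize("n,k", [(3, 4), (5, 1)])
    def test_invalid_k(self, n, k):
        with pytest.raises(ValueError):
            kfold_split(list(range(n)), k)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(2, 60), k=st.integers(2, 8))
    def test_partition_property(self, n, k):
        if k > n:
            return
        split = kfold_split(list(range(n)), k)
        seen = []
        for train_ids, val_ids in split.folds:
            assert sorted(train_ids + val_ids) == list(range(n))
            seen.extend(val_ids)
        assert sorted(seen) == list(range(n))  # exactly one val fold each
        sizes = [len(v) for _, v in split.folds]
        assert max(sizes) - min(sizes) <= 1
        assert sizes == sorted(sizes, reverse=True)


def _micro_pairs(rng, n=1, shape=(8, 8, 4)):
    pairs = []
    for _ in range(n):
        data = rng.random(shape, dtype=np.float32) + 0.1
        mask = np.zeros(shape, np.uint8)
        mask[2:5, 2:5, 1:3] = 1
        pairs.append((Volume(data), Mask(mask)))
    return pairs


class TestTrainLoop:
    def test_never_improving_metric_stops_after_patience_plus_one(self, rng):
        model = build_model(VNetConfig.tiny(dims=3, n_channels=2), seed=0)
        pairs = _micro_pairs(rng)
        cfg = TrainConfig(max_iterations=1000, validate_every=1, patience=1,
                          seed=0)
        rec = train(model, pairs, pairs, cfg, val_metric=lambda m: 0.5)
        assert len(rec.history) == 2  # initial epoch + 1 without improvement
        assert rec.n_iterations == 2
        assert rec.val_dsc == 0.5

    def test_exactly_one_validation_epoch(self, rng):
        model = build_model(VNetConfig.tiny(dims=3, n_channels=2), seed=0)
        pairs = _micro_pairs(rng)
        cfg = TrainConfig(max_iterations=90, validate_every=90, patience=30,
                          seed=0)
        rec = train(model, pairs, pairs, cfg, val_metric=lambda m: 0.5)
        assert len(rec.history) == 1
        assert rec.n_iterations == 90

    def test_nonfinite_loss_raises_with_iteration(self, rng):
        model = build_model(VNetConfig.tiny(dims=3, n_channels=2), seed=0)
        for _, w, _ in model.parameters():
            w[...] = np.nan
        pairs = _micro_pairs(rng)
        with pytest.raises(TrainingError, match="iteration 0"):
            train(model, pairs, pairs, TrainConfig(max_iterations=5,
                                                   validate_every=5))

    def test_empty_sets_rejected(self, rng):
        model = build_model(VNetConfig.tiny(dims=3, n_channels=2), seed=0)
        with pytest.raises(ValueError):
            train(model, [], _micro_pairs(rng), TrainConfig())

    def test_best_checkpoint_restored(self, rng):
        # metric rises then falls: the returned model carries the weights
        # from the best epoch, and val_dsc reports the peak
        model = build_model(VNetConfig.tiny(dims=3, n_channels=2), seed=0)
        pairs = _micro_pairs(rng)
        series = iter([0.2, 0.9, 0.3, 0.1, 0.1, 0.1])
        cfg = TrainConfig(max_iterations=100, validate_every=1, patience=3,
                          seed=0)
        rec = train(model, pairs, pairs, cfg,
                    val_metric=lambda m: next(series))
        assert rec.val_dsc == 0.9
        assert len(rec.history) == 5  # peak at epoch 2 + 3 patience epochs

    def test_seeded_training_is_reproducible(self, rng):
        pairs = _micro_pairs(rng)
        cfg = TrainConfig(max_iterations=6, validate_every=3, seed=11)
        recs = []
        for _ in range(2):
            model = build_model(VNetConfig.tiny(dims=3, n_channels=2),
                                seed=4)
            recs.append(train(model, pairs, pairs, cfg))
        assert recs[0].val_dsc == recs[1].val_dsc
        for (_, wa, _), (_, wb, _) in zip(recs[0].model.parameters(),
                                          recs[1].model.parameters()):
            np.testing.assert_array_equal(wa, wb)


def _record(mid, dsc, model=None):
    return TrainedModelRecord(model_id=mid, model=model, val_dsc=dsc)


class TestEnsemble:
    def test_filter_excludes_below_threshold(self):
        records = [_record("a", 0.86), _record("b", 0.65), _record("c", 0.72)]
        e = build_ensemble(records, threshold=0.70)
        assert [m.model_id for m in e.members] == ["a", "c"]
        assert e.excluded == ("b",)

    def test_40_records_4_at_or_below_gate(self):
        dscs = [0.75 + 0.002 * i for i in range(36)] + [0.70, 0.65, 0.5, 0.70]
        records = [_record(f"m{i}", d) for i, d in enumerate(dscs)]
        e = build_ensemble(records, threshold=0.70)
        assert len(e.members) == 36
        assert len(e.excluded) == 4

    def test_gate_is_strict(self):
        with pytest.raises(EmptyEnsembleError):
            build_ensemble([_record("a", 0.70)], threshold=0.70)

    def test_all_below_threshold_rejected(self):
        with pytest.raises(EmptyEnsembleError):
            build_ensemble([_record("a", 0.5), _record("b", 0.5)])

    def test_fusion_mean_and_bounds(self, rng, monkeypatch):
        v = Volume(rng.random((8, 8, 4), dtype=np.float32))
        constant = {"lo": 0.2, "hi": 0.8}

        def fake_predict(record, vol):
            return ProbMap(np.full(vol.shape, constant[record.model_id],
                                   np.float32), vol.spacing)

        monkeypatch.setattr(tr, "full_volume_predict", fake_predict)
        e = build_ensemble([_record("lo", 0.8), _record("hi", 0.9)])
        fused = ensemble_predict(e, v)
        np.testing.assert_allclose(fused.data, 0.5)

    def test_real_models_permutation_invariant_and_bounded(self, rng):
        v = Volume(rng.random((8, 8, 4), dtype=np.float32))
        models = [build_model(VNetConfig.tiny(dims=3, n_channels=2), seed=s)
                  for s in (0, 1, 2)]
        records = [_record(f"m{i}", 0.9, m) for i, m in enumerate(models)]
        maps = [tr.full_volume_predict(r, v).data for r in records]
        fused = ensemble_predict(build_ensemble(records), v)
        permuted = ensemble_predict(build_ensemble(records[::-1]), v)
        np.testing.assert_allclose(fused.data, permuted.data, atol=1e-7)
        stack = np.stack(maps)
        assert (fused.data >= stack.min(axis=0) - 1e-6).all()
        assert (fused.data <= stack.max(axis=0) + 1e-6).all()

    def test_single_member_identity(self, rng):
        v = Volume(rng.random((8, 8, 4), dtype=np.float32))
        model = build_model(VNetConfig.tiny(dims=3, n_channels=2), seed=0)
        rec = _record("solo", 0.9, model)
        fused = ensemble_predict(build_ensemble([rec]), v)
        np.testing.assert_allclose(fused.data,
                                   tr.full_volume_predict(rec, v).data)
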