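"""Training orchestration: determinism, freezing, folds, ensembling."""

from dataclasses import replace

import numpy as np
import pytest

from supcon_tsc import (EncoderConfig, SyntheticSpec, TrainConfig, fit_two_stage,
                        kfold_ensemble, make_mtsc, predict_ensemble,
                        pretrain_representation, train_classifier)
from supcon_tsc.trainer import TrainedModel


def small_cfg(**kw):
    enc = EncoderConfig(block_filters=(4, 8, 8), kernel_sizes=(5, 3, 3),
                        proj_dim=8, proj_hidden=16, clf_hidden=16)
    defaults = dict(batch_size=12, epochs=4, warmup=1, tau=0.1, encoder=enc,
                    seed=3, stage2_epochs=30, bank_capacity=4)
    defaults.update(kw)
    return TrainConfig(**defaults)


@pytest.fixture(scope="module")
def small_ds():
    return make_mtsc(SyntheticSpec(n_classes=3, n_per_class=12, m=2, l=24,
                                   intra_var=0.2, inter_sim=0.1, seed=21))


class TestPretrain:
    def test_trace_schema_and_alpha(self, small_ds):
        cfg = small_cfg(epochs=4, warmup=2)
        res = pretrain_representation(small_ds, cfg)
        assert len(res.trace) == 4
        assert [r["alpha"] for r in res.trace] == [0, 0, 1, 1]
        assert all(np.isfinite(r["instance_loss"]) for r in res.trace)

    def test_warmup_equals_epochs_disables_cluster_term(self, small_ds):
        res = pretrain_representation(small_ds, small_cfg(epochs=3, warmup=3))
        assert all(r["alpha"] == 0 for r in res.trace)
        assert all(r["cluster_loss"] == 0.0 for r in res.trace)

    def test_determinism_same_seed(self, small_ds):
        a = pretrain_representation(small_ds, small_cfg(seed=7))
        b = pretrain_representation(small_ds, small_cfg(seed=7))
        assert a.trace == b.trace
        for pa, pb in zip(a.model.net.state_arrays(), b.model.net.state_arrays()):
            np.testing.assert_array_equal(pa, pb)

    def test_instance_loss_decreases(self, small_ds):
        res = pretrain_representation(small_ds, small_cfg(epochs=8, warmup=2, seed=1))
        assert res.trace[-1]["instance_loss"] < res.trace[0]["instance_loss"]

    def test_batch_size_exceeding_n_rejected(self, small_ds):
        with pytest.raises(ValueError, match="batch_size"):
            pretrain_representation(small_ds, small_cfg(batch_size=1000))


class TestStageTwo:
    def test_encoder_frozen_bit_identical(self, small_ds):
        cfg = small_cfg()
        pre = pretrain_representation(small_ds, cfg)
        before_enc = [a.copy() for blk in pre.model.net.encoder_modules()
                      for a in blk.state_arrays()]
        before_clf = [p.data.copy() for p in pre.model.net.classifier_parameters()]
        res = train_classifier(small_ds, pre, cfg)
        after_enc = [a for blk in res.model.net.encoder_modules()
                     for a in blk.state_arrays()]
        for x, y in zip(before_enc, after_enc):
            np.testing.assert_array_equal(x, y)  # frozen: bit-identical
        moved = [not np.array_equal(x, p.data) for x, p in
                 zip(before_clf, res.model.net.classifier_parameters())]
        assert any(moved)  # classifier actually trained

    def test_stage2_loss_decreases(self, small_ds):
        cfg = small_cfg()
        res = fit_two_stage(small_ds, cfg)
        assert res.stage2_trace[-1]["loss"] < res.stage2_trace[0]["loss"]

    def test_separable_features_reach_high_train_accuracy(self):
        ds = make_mtsc(SyntheticSpec(n_classes=2, n_per_class=15, m=2, l=24,
                                     intra_var=0.1, seed=5))
        cfg = small_cfg(epochs=6, warmup=1, stage2_epochs=60, seed=2)
        res = fit_two_stage(ds, cfg)
        acc = (res.model.predict(ds.values, ds.mask) == ds.labels).mean()
        assert acc == pytest.approx(1.0)

    def test_baseline_path_skips_head_and_bank(self, small_ds):
        cfg = small_cfg(with_supcon=False)
        res = train_classifier(small_ds, None, cfg)
        assert res.trace == []  # no stage-1 trace: bank and head never used
        assert len(res.stage2_trace) == cfg.n_baseline_epochs
        fresh = TrainedModel(res.model.net, res.model.norm_stats, res.model.class_names)
        assert fresh.predict(small_ds.values, small_ds.mask).shape == (small_ds.n,)

    def test_missing_pretrain_rejected(self, small_ds):
        with pytest.raises(ValueError, match="pretrained"):
            train_classifier(small_ds, None, small_cfg(with_supcon=True))


class TestKFold:
    def test_stratified_fold_arithmetic(self):
        ds = make_mtsc(SyntheticSpec(n_classes=3, n_per_class=10, m=2, l=16,
                                     intra_var=0.1, seed=4))
        cfg = small_cfg(epochs=2, warmup=1, stage2_epochs=10, k_folds=5, batch_size=8)
        results = kfold_ensemble(ds, cfg)
        assert len(results) == 5
        assert all(r.val_accuracy is not None for r in results)
        assert sorted(r.fold_id for r in results) == [0, 1, 2, 3, 4]

    def test_class_smaller_than_k_rejected(self):
        ds = make_mtsc(SyntheticSpec(n_classes=2, n_per_class=3, m=2, l=16, seed=1))
        with pytest.raises(ValueError, match="class_0"):
            kfold_ensemble(ds, small_cfg(k_folds=5, batch_size=4))

    def test_fold_assignment_deterministic(self):
        from sklearn.model_selection import StratifiedKFold

        from supcon_tsc._rng import child_seed
        y = np.repeat([0, 1, 2], 10)
        s = child_seed(3, "folds") % (2 ** 31)
        a = list(StratifiedKFold(5, shuffle=True, random_state=s).split(np.zeros((30, 1)), y))
        b = list(StratifiedKFold(5, shuffle=True, random_state=s).split(np.zeros((30, 1)), y))
        for (tra, va), (trb, vb) in zip(a, b):
            np.testing.assert_array_equal(va, vb)


class TestEnsemble:
    class _Stub:
        def __init__(self, probs, names=("a", "b")):
            self._p = np.asarray(probs, dtype=float)
            self.class_names = list(names)

        def predict_proba(self, values, mask=None):
            return self._p

    def test_identical_models_equal_single(self):
        p = [[0.7, 0.3], [0.2, 0.8]]
        labels, probs = predict_ensemble([self._Stub(p), self._Stub(p)], np.zeros((2, 1, 4)))
        np.testing.assert_allclose(probs, p)
        assert labels.tolist() == [0, 1]

    def test_probability_averaging(self):
        a, b = self._Stub([[0.6, 0.4]]), self._Stub([[0.2, 0.8]])
        labels, probs = predict_ensemble([a, b], np.zeros((1, 1, 4)))
        np.testing.assert_allclose(probs, [[0.4, 0.6]])
        assert labels.tolist() == [1]

    def test_exact_tie_breaks_to_lowest_id(self):
        labels, _ = predict_ensemble([self._Stub([[0.5, 0.5]])], np.zeros((1, 1, 4)))
        assert labels.tolist() == [0]

    def test_inconsistent_class_maps_rejected(self):
        with pytest.raises(ValueError, match="class mapping"):
            predict_ensemble([self._Stub([[1, 0]]), self._Stub([[1, 0]], names=("x", "y"))],
                             np.zeros((1, 1, 4)))


def test_reproducible_predictions_end_to_end(small_ds):
    cfg = small_cfg(seed=11, epochs=3, stage2_epochs=20)
    a = fit_two_stage(small_ds, cfg)
    b = fit_two_stage(small_ds, cfg)
    np.testing.assert_array_equal(a.model.predict(small_ds.values, small_ds.mask),
                                  b.model.predict(small_ds.values, small_ds.mask))
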