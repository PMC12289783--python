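"""Tests for splitting, metrics, the training loop and checkpoints."""

import numpy as np
import pytest

from ddunet.metrics import ConfusionCounts, confusion, metrics
from ddunet.model import DualDecoderUNet, ModelConfig
from ddunet.nn import Tensor
from ddunet.synthetic import SyntheticConfig, generate_dataset
from ddunet.train import (
    TrainConfig, eam_auxiliary_loss, evaluate, kfold_split, load_checkpoint,
    save_checkpoint, split_dataset, train, training_loss,
)


@pytest.fixture(scope="module")
def small_data():
    return generate_dataset(SyntheticConfig(n_images=8, image_size=32, seed=6))


@pytest.fixture(scope="module")
def tiny_cfg():
    return ModelConfig.tiny(32)


class TestSplitting:
    def test_eighty_ten_ten_on_hundred(self):
        data = list(range(100))
        tr, va, te = split_dataset(data, (0.8, 0.1, 0.1), seed=0)
        assert (len(tr), len(va), len(te)) == (80, 10, 10)
        assert sorted(tr + va + te) == data

    def test_split_reproducible_per_seed(self):
        data = list(range(30))
        assert split_dataset(data, seed=5) == split_dataset(data, seed=5)
        assert split_dataset(data, seed=5) != split_dataset(data, seed=6)

    def test_kfold_disjoint_exhaustive(self):
        data = list(range(50))
        folds = kfold_split(data, 5, seed=1)
        assert [len(f) for f in folds] == [10] * 5
        flat = [x for f in folds for x in f]
        assert sorted(flat) == data
        assert kfold_split(data, 5, seed=1) == kfold_split(data, 5, seed=1)

    def test_kfold_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(list(range(3)), 5)

    def test_bad_split_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(10)), (0.8, 0.3, 0.1))


class TestConfusionMetrics:
    def test_exhaustive_small_example(self):
        c = confusion(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0]))
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)
        m = metrics(c)
        assert m["precision"] == 0.5 and m["recall"] == 0.5
        assert m["iou"] == pytest.approx(1 / 3) and m["dsc"] == 0.5

    def test_perfect_and_inverted_predictions(self):
        gt = np.array([1, 0, 1, 1, 0])
        c = confusion(gt, gt)
        assert c.fp == 0 and c.fn == 0
        assert all(v == 1.0 for v in metrics(c).values())
        c_inv = confusion(1 - gt, gt)
        assert c_inv.tp == 0 and c_inv.tn == 0

    def test_verbatim_formulas_are_swapped(self):
        c = ConfusionCounts(1, 1, 1, 1)
        std, ver = metrics(c, "standard"), metrics(c, "verbatim")
        assert ver["iou"] == std["dsc"] == 0.5
        assert ver["dsc"] == std["iou"] == pytest.approx(1 / 3)

    def test_empty_denominator_convention(self):
        all_neg = ConfusionCounts(0, 0, 0, 10)
        assert metrics(all_neg)["recall"] == 1.0  # agreement
        missed = ConfusionCounts(0, 0, 3, 7)
        assert metrics(missed)["precision"] == 0.0  # nothing predicted, fn>0

    def test_shape_and_binary_validation(self):
        with pytest.raises(ValueError):
            confusion(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            confusion(np.zeros(3), np.array([0, 1, 2]))


class TestTrainingLoop:
    def test_zero_lr_leaves_parameters_unchanged(self, small_data, tiny_cfg):
        res = train(small_data, tiny_cfg,
                    TrainConfig(max_epochs=2, batch_size=4, lr=0.0, seed=0))
        fresh = DualDecoderUNet(tiny_cfg)
        for (_, p), (_, q) in zip(res.model.named_parameters(),
                                  fresh.named_parameters()):
            np.testing.assert_allclose(p.data, q.data.astype(p.data.dtype),
                                       atol=1e-7)

    def test_same_seed_gives_identical_loss_curves(self, small_data, tiny_cfg):
        cfg = TrainConfig(max_epochs=3, batch_size=4, seed=9)
        a = train(small_data, tiny_cfg, cfg)
        b = train(small_data, tiny_cfg, cfg)
        assert [h["loss_total"] for h in a.history] == \
               [h["loss_total"] for h in b.history]

    def test_best_val_loss_never_increases(self, small_data, tiny_cfg):
        res = train(small_data, tiny_cfg,
                    TrainConfig(max_epochs=5, batch_size=4, seed=3))
        vals = [h["val_loss"] for h in res.history if np.isfinite(h["val_loss"])]
        assert res.best_val_loss == min(vals)

    def test_empty_dataset_rejected(self, tiny_cfg):
        with pytest.raises(ValueError, match="empty"):
            train([], tiny_cfg, TrainConfig(max_epochs=1))

    def test_nonfinite_loss_abort_names_component(self, small_data, tiny_cfg):
        from ddunet.model import DecoderOutputs
        m = DualDecoderUNet(tiny_cfg)
        out = m(np.stack([p.image for p in small_data[:2]])[:, None])
        bad = DecoderOutputs(M_F=Tensor(np.full_like(out.M_F.data, np.nan)),
                             M_B=out.M_B, O_Final=out.O_Final, eam=out.eam)
        y = np.stack([p.mask for p in small_data[:2]])[:, None].astype(float)
        with pytest.raises(RuntimeError, match="loss"):
            training_loss(bad, y)

    def test_training_reduces_loss(self, small_data, tiny_cfg):
        res = train(small_data, tiny_cfg,
                    TrainConfig(max_epochs=6, batch_size=4, seed=1))
        assert res.history[-1]["loss_total"] < res.history[0]["loss_total"]

    def test_auxiliary_loss_supervises_candidates(self, small_data, tiny_cfg):
        m = DualDecoderUNet(tiny_cfg)
        x = np.stack([p.image for p in small_data[:2]])[:, None]
        y = np.stack([p.mask for p in small_data[:2]])[:, None].astype(float)
        out = m(x)
        aux = eam_auxiliary_loss(out.eam, y)
        assert np.isfinite(float(aux)) and float(aux) > 0


class TestEvaluateAndCheckpoint:
    def test_evaluate_reports_per_image_and_macro(self, small_data, tiny_cfg):
        m = DualDecoderUNet(tiny_cfg).eval()
        rows, agg = evaluate(m, small_data[:4])
        assert len(rows) == 4
        assert set(agg) == {"precision", "recall", "iou", "dsc"}

    def test_evaluate_empty_set_gives_empty_report(self, tiny_cfg):
        m = DualDecoderUNet(tiny_cfg).eval()
        rows, agg = evaluate(m, [])
        assert rows == [] and agg == {}

    def test_checkpoint_roundtrip_preserves_predictions(self, small_data,
                                                        tiny_cfg, tmp_path):
        res = train(small_data, tiny_cfg,
                    TrainConfig(max_epochs=2, batch_size=4, seed=2))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, res.model, epoch=2, last_loss=1.0)
        loaded, meta = load_checkpoint(path)
        assert meta["epoch"] == 2
        x = small_data[0].image
        np.testing.assert_allclose(loaded(x).O_Final.data,
                                   res.model(x).O_Final.data, atol=1e-6)
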