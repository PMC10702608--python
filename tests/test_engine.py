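"""Training loop, inference stitching, evaluation and checkpointing."""

import numpy as np
import pytest

from mfaunet import engine, metrics
from mfaunet.network import ModelConfig, build_model
from mfaunet.synthfundus import SynthConfig, make_dataset


TINY = dict(encoder_channels=(4, 8, 16, 32), msam_mlp_ratio=0.5,
            pam_reduction=2, mbdm_branch_channels=2, head_channels=4)


def tiny_cfg(seed=0, **kw):
    return ModelConfig(**{**TINY, **kw, "seed": seed})


def tiny_patches(rng, n=40, w=32, groups=4):
    """Small synthetic patch pool: bright background, dark bars."""
    x = rng.random((n, 1, w, w)).astype(np.float32) * 0.1 + 0.6
    y = np.zeros_like(x)
    for i in range(n):
        c = rng.integers(4, w - 4)
        y[i, 0, :, c - 1:c + 1] = 1.0
        x[i, 0, :, c - 1:c + 1] -= 0.35
    g = np.arange(n) % groups
    return x, y, g


@pytest.fixture(scope="module")
def trained(tmp_path_factory):
    """A 2-epoch training run shared by several tests."""
    rng = np.random.default_rng(0)
    x, y, g = tiny_patches(rng)
    tcfg = engine.TrainConfig(epochs=2, batch_size=8, lr=1e-3, augment=False,
                              val_fraction=0.25, seed=3)
    ckpt = tmp_path_factory.mktemp("ckpt") / "model.npz"
    model, record = engine.train(tiny_cfg(3), tcfg, (x, y, g),
                                 checkpoint_path=ckpt)
    return model, record, ckpt, (x, y, g)


class TestTrain:
    def test_smoke_run_records_every_epoch(self, trained):
        _, record, _, _ = trained
        assert len(record.epochs) == 2
        assert record.best_epoch in (0, 1)
        assert np.isfinite(record.epochs[-1].train_loss)

    def test_split_is_disjoint_by_source_image(self):
        groups = np.repeat(np.arange(6), 5)
        tr, va = engine.split_by_image(groups, 0.2, np.random.default_rng(0))
        assert set(groups[tr]).isdisjoint(set(groups[va]))
        assert len(tr) + len(va) == len(groups)

    def test_same_seed_reproduces_loss_trajectory(self):
        rng = np.random.default_rng(1)
        x, y, g = tiny_patches(rng, n=24)
        tcfg = engine.TrainConfig(epochs=2, batch_size=8, lr=1e-3,
                                  augment=False, val_fraction=0.25, seed=5)
        _, rec_a = engine.train(tiny_cfg(5), tcfg, (x, y, g))
        _, rec_b = engine.train(tiny_cfg(5), tcfg, (x, y, g))
        for ea, eb in zip(rec_a.epochs, rec_b.epochs):
            assert abs(ea.train_loss - eb.train_loss) < 1e-6

    def test_learning_reduces_training_loss(self):
        rng = np.random.default_rng(7)
        x, y, g = tiny_patches(rng, n=48)
        tcfg = engine.TrainConfig(epochs=5, batch_size=8, lr=2e-3,
                                  augment=False, val_fraction=0.25, seed=7)
        _, rec = engine.train(tiny_cfg(7), tcfg, (x, y, g))
        assert rec.epochs[4].train_loss < rec.epochs[0].train_loss

    def test_empty_dataset_raises(self):
        tcfg = engine.TrainConfig(epochs=1)
        with pytest.raises(ValueError):
            engine.train(tiny_cfg(), tcfg,
                         (np.zeros((0, 1, 32, 32)), np.zeros((0, 1, 32, 32)),
                          np.zeros(0)))

    def test_lr_schedule_decays(self):
        tcfg = engine.TrainConfig(lr=1e-3, lr_decay=0.1, lr_decay_every=2,
                                  epochs=4, batch_size=8, augment=False,
                                  val_fraction=0.25, seed=0)
        rng = np.random.default_rng(2)
        x, y, g = tiny_patches(rng, n=16)
        _, rec = engine.train(tiny_cfg(), tcfg, (x, y, g))
        assert rec.epochs[0].lr == pytest.approx(1e-3)
        assert rec.epochs[2].lr == pytest.approx(1e-4)


class _StubModel:
    """Predicts a constant probability; mimics the MFAUNet surface."""

    def __init__(self, value):
        self.value = value

    def eval(self):
        return self

    def predict_proba(self, x):
        return np.full((x.shape[0], 1, x.shape[2], x.shape[3]), self.value,
                       dtype=np.float32)


class TestPredictImage:
    def test_constant_stub_yields_constant_map(self):
        img = np.full((80, 90, 3), 120, dtype=np.uint8)
        prob = engine.predict_image(_StubModel(0.7), img, window=32, stride=16)
        assert prob.shape == (80, 90)
        np.testing.assert_allclose(prob, 0.7, atol=1e-6)

    def test_probabilities_within_unit_interval(self, trained):
        model = trained[0]
        img, _, _, _ = __import__("mfaunet.synthfundus", fromlist=["generate_sample"]).generate_sample(
            SynthConfig(seed=1, image_size=96))
        prob = engine.predict_image(model, img, window=32, stride=16)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_image_smaller_than_window_is_padded_and_cropped(self):
        img = np.full((20, 24, 3), 100, dtype=np.uint8)
        prob = engine.predict_image(_StubModel(0.3), img, window=32, stride=16)
        assert prob.shape == (20, 24)


class TestEvaluateDataset:
    def _dataset(self, tmp_path, n=2):
        make_dataset(SynthConfig(seed=21, image_size=96), n, tmp_path)
        return engine.load_dataset(tmp_path)

    def test_perfect_probability_map_scores_one(self, tmp_path):
        samples = self._dataset(tmp_path)
        rep = metrics.evaluate_probability_map(
            samples[0]["mask"].astype(np.float32), samples[0]["mask"])
        assert rep.acc == 1.0 and rep.dsc == 1.0

    def test_report_schema_and_pooled_additivity(self, tmp_path, trained):
        model = trained[0]
        samples = self._dataset(tmp_path, n=3)
        rep = engine.evaluate_dataset(model, samples, window=32, stride=16)
        assert len(rep["per_image"]) == 3
        for key in ("acc", "dsc", "se", "sp", "auc"):
            assert key in rep["pooled"]
        assert 0.0 <= rep["msen"] <= 1.0 and 0.0 <= rep["msp"] <= 1.0
        # pooled accuracy equals the ratio of pooled counts
        counts = [metrics.confusion(
            metrics.binarize(engine.predict_image(model, s["image"],
                                                  window=32, stride=16)),
            s["mask"]) for s in samples]
        pooled = counts[0] + counts[1] + counts[2]
        assert rep["pooled"]["acc"] == pytest.approx(
            (pooled.tp + pooled.tn) / pooled.n)


class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, trained):
        model, _, ckpt, (x, _, _) = trained
        reloaded = engine.load_checkpoint(ckpt)
        a = model.eval().predict_proba(x[:4])
        b = reloaded.predict_proba(x[:4])
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_cross_evaluate_matches_evaluate_on_same_data(self, trained, tmp_path):
        model, _, ckpt, _ = trained
        make_dataset(SynthConfig(seed=31, image_size=96), 2, tmp_path)
        a = engine.cross_evaluate(ckpt, tmp_path, window=32, stride=16)
        b = engine.evaluate_dataset(model, tmp_path, window=32, stride=16)
        assert a["pooled"] == b["pooled"]

    def test_mismatched_architecture_rejected(self, trained, tmp_path):
        _, _, ckpt, _ = trained
        other = build_model(tiny_cfg(0, encoder_channels=(4, 8, 16, 64)))
        import numpy as _np
        with _np.load(ckpt) as z:
            arrays = {k: z[k] for k in z.files if k != "__meta__"}
        with pytest.raises(ValueError):
            other.load_state_dict(arrays)


class TestMiniatureProtocol:
    def test_patch_pools_have_requested_sizes(self):
        x, y, g, vi = engine.make_miniature_patches(3, n_train=60, n_val=12,
                                                    window=64)
        assert len(x) == 72
        val = set(vi)
        assert sum(gi in val for gi in g) == 12
        assert sum(gi not in val for gi in g) == 60
        assert x.shape[1:] == (1, 64, 64)
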