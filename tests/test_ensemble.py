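import numpy as np
import pytest

from celltyper import (
    AugmentationConfig,
    ClassDef,
    ConfigurationError,
    CropSpec,
    MarkerRule,
    ModelConfig,
    SamplerConfig,
    TissueConfig,
    ensemble_predict,
    filter_by_confidence,
    generate_tissue,
    load_model,
    predict_bundle,
    save_model,
    train_model,
)
from celltyper.data_io import CellTable, DatasetBundle
from celltyper.ensemble import DEFAULT_CONFIDENCE_CUTOFF, DEFAULT_ENSEMBLE_SIZE, TrainedModel, build_tensors
from celltyper.nn import Adam, SmallCNN, softmax_cross_entropy

from conftest import tiny_tissue_config


def _bundle(n_classes=2, n_cells=80, seed=0, **kw):
    cfg = tiny_tissue_config(n_classes=n_classes, n_cells=n_cells, **kw)
    stack, mask, table = generate_tissue(cfg, np.random.default_rng(seed))
    return DatasetBundle({stack.fov_id: (stack, mask)}, table)


def _model_cfg(bundle, **kw):
    kw.setdefault("epochs", 3)
    kw.setdefault("draws_per_epoch", 120)
    return ModelConfig(n_classes=len(bundle.vocabulary),
                       input_channels=len(bundle.channels) + 2, **kw)


CROP = CropSpec(16)
NO_AUG = AugmentationConfig.none()


class TestEngine:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = SmallCNN(2, 3, rng, widths=(4, 6, 8))
        x = rng.standard_normal((2, 2, 8, 8))
        y = np.array([0, 2])
        logits = net.forward(x)
        _, dlogits = softmax_cross_entropy(logits, y)
        net.zero_grad()
        net.backward(dlogits)
        name, p, g = net.parameters()[0]
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (1, 1, 1, 1), (3, 1, 2, 0)]:
            p[idx] += eps
            up, _ = softmax_cross_entropy(net.forward(x), y)
            p[idx] -= 2 * eps
            dn, _ = softmax_cross_entropy(net.forward(x), y)
            p[idx] += eps
            fd = (up - dn) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_adam_reduces_loss_on_fixed_batch(self):
        rng = np.random.default_rng(1)
        net = SmallCNN(2, 2, rng, widths=(4, 4, 8))
        opt = Adam(net, lr=1e-2)
        x = rng.standard_normal((8, 2, 8, 8))
        y = np.array([0, 1] * 4)
        first, _ = softmax_cross_entropy(net.forward(x), y)
        for _ in range(30):
            logits = net.forward(x)
            _, dlogits = softmax_cross_entropy(logits, y)
            net.zero_grad()
            net.backward(dlogits)
            opt.step()
        last, _ = softmax_cross_entropy(net.forward(x), y)
        assert last < first / 2


class TestTrainModel:
    def test_same_seed_gives_bitwise_identical_predictions(self):
        bundle = _bundle()
        probes = build_tensors(bundle, bundle.cells.labeled()[:10], CROP)
        runs = []
        for _ in range(2):
            m = train_model(bundle, CROP, AugmentationConfig(), SamplerConfig(),
                            _model_cfg(bundle), seed=3)
            runs.append(m.predict_proba(probes))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_separable_two_class_training_recall(self):
        # distinct nuclear markers per class are separable by construction
        bundle = _bundle(n_classes=2, n_cells=120, image_shape=(224, 224))
        m = train_model(bundle, CROP, NO_AUG, SamplerConfig(),
                        _model_cfg(bundle, epochs=5, draws_per_epoch=200), seed=0)
        preds = ensemble_predict([m], build_tensors(bundle, bundle.cells.labeled(), CROP))
        truth = {(r.fov_id, r.cell_id): r.label for r in bundle.cells.labeled()}
        for cls in bundle.vocabulary:
            cells = [p for p in preds if truth[(p.fov_id, p.cell_id)] == cls]
            recall = np.mean([p.predicted_label == cls for p in cells])
            assert recall >= 0.99

    def test_epoch_range_accepted_without_warning(self, recwarn):
        ModelConfig(n_classes=2, epochs=10)
        ModelConfig(n_classes=2, epochs=40)
        assert len(recwarn) == 0
        with pytest.raises(ConfigurationError):
            ModelConfig(n_classes=2, epochs=0)

    def test_class_absent_from_labels_raises(self):
        bundle = _bundle()
        stripped = [r for r in bundle.cells.records if r.label != bundle.vocabulary[0]]
        broken = DatasetBundle(bundle.fovs,
                               CellTable(stripped, list(bundle.vocabulary)))
        with pytest.raises(ConfigurationError, match="absent"):
            train_model(broken, CROP, NO_AUG, SamplerConfig(), _model_cfg(bundle),
                        seed=0)

    def test_resnet50_backbone_unavailable(self):
        cfg = ModelConfig(backbone="resnet50", n_classes=2)
        with pytest.raises(ConfigurationError, match="small_cnn"):
            cfg.make_net(np.random.default_rng(0))

    def test_training_log_has_loss_per_epoch(self):
        bundle = _bundle()
        m = train_model(bundle, CROP, NO_AUG, SamplerConfig(), _model_cfg(bundle),
                        seed=0)
        assert list(m.log["epoch"]) == [0, 1, 2]
        assert {"train_loss", "val_loss", "val_recall"} <= set(m.log.columns)


class _Stub(TrainedModel):
    """Fixed-output model for ensemble arithmetic tests."""

    def __init__(self, probs, vocab):
        net = SmallCNN(3, len(vocab), np.random.default_rng(0), widths=(2, 2, 2))
        cfg = ModelConfig(n_classes=len(vocab), input_channels=3)
        super().__init__(net, cfg, list(vocab), 0)
        self._probs = np.asarray(probs, dtype=float)

    def predict_proba(self, tensors):
        return np.tile(self._probs, (len(tensors), 1))


def _dummy_tensors(n=1):
    from celltyper.tensorization import CropTensor

    return [
        CropTensor(np.zeros((3, 8, 8), dtype=np.float32),
                   ["a", "target_mask", "environment_mask"], "fov0", i + 1)
        for i in range(n)
    ]


class TestEnsemblePredict:
    def test_copies_of_one_model_equal_single_model(self):
        m = _Stub([0.3, 0.7], ["a", "b"])
        single = ensemble_predict([m], _dummy_tensors())[0]
        multi = ensemble_predict([m, m, m], _dummy_tensors())[0]
        np.testing.assert_array_equal(single.probabilities, multi.probabilities)

    def test_two_model_average(self):
        a = _Stub([0.6, 0.4], ["x", "y"])
        b = _Stub([0.2, 0.8], ["x", "y"])
        p = ensemble_predict([a, b], _dummy_tensors())[0]
        np.testing.assert_allclose(p.probabilities, [0.4, 0.6])
        assert p.predicted_label == "y"
        assert p.confidence == pytest.approx(0.6)

    def test_averaged_probabilities_sum_to_one(self):
        a = _Stub([0.5, 0.3, 0.2], ["x", "y", "z"])
        b = _Stub([0.1, 0.1, 0.8], ["x", "y", "z"])
        for p in ensemble_predict([a, b], _dummy_tensors(5)):
            assert abs(p.probabilities.sum() - 1.0) < 1e-6

    def test_argmax_tie_breaks_to_lowest_index(self):
        p = ensemble_predict([_Stub([0.5, 0.5], ["a", "b"])], _dummy_tensors())[0]
        assert p.predicted_label == "a"

    def test_vocabulary_mismatch_raises(self):
        a = _Stub([0.5, 0.5], ["x", "y"])
        b = _Stub([0.5, 0.5], ["x", "z"])
        with pytest.raises(ConfigurationError):
            ensemble_predict([a, b], _dummy_tensors())

    def test_default_ensemble_size_is_ten(self):
        assert DEFAULT_ENSEMBLE_SIZE == 10


class TestFilterByConfidence:
    def _preds(self, confs):
        out = []
        for i, c in enumerate(confs):
            out.append(ensemble_predict([_Stub([c, 1 - c], ["a", "b"])],
                                        _dummy_tensors())[0])
        return out

    def test_cutoff_zero_keeps_everything(self):
        preds = self._preds([0.9, 0.55])
        kept, cov = filter_by_confidence(preds, 0.0)
        assert len(kept) == 2 and cov == 1.0

    def test_counting_at_cutoff(self):
        preds = self._preds([0.9, 0.6, 0.71])
        kept, cov = filter_by_confidence(preds, 0.7)
        assert len(kept) == 2
        assert cov == pytest.approx(2 / 3)

    def test_empty_input_gives_nan_with_warning(self):
        with pytest.warns(UserWarning):
            kept, cov = filter_by_confidence([], 0.5)
        assert kept == [] and np.isnan(cov)

    def test_default_cutoff(self):
        assert DEFAULT_CONFIDENCE_CUTOFF == 0.7


def test_checkpoint_round_trip(tmp_path):
    bundle = _bundle()
    m = train_model(bundle, CROP, NO_AUG, SamplerConfig(), _model_cfg(bundle), seed=1)
    save_model(m, tmp_path / "member_1")
    loaded = load_model(tmp_path / "member_1")
    probes = build_tensors(bundle, bundle.cells.labeled()[:5], CROP)
    np.testing.assert_array_equal(m.predict_proba(probes), loaded.predict_proba(probes))
    assert loaded.vocabulary == m.vocabulary
    assert loaded.seed == m.seed
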