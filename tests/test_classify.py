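"""Training harness: LR schedule, log shape, gradient correctness,
confusion-matrix metrics (including the published worked example)."""
import numpy as np
import pytest

from periseg.classify import (CLASSES, ConfusionMatrix, LOG_COLUMNS,
                              TrainConfig, build_model, evaluate,
                              learning_rate_schedule, metrics_from_confusion,
                              predict, prepare_tiles, train, save_model,
                              load_model, _softmax_xent)
from periseg.dataset import split
from periseg.mask import ToothTile
from periseg.segment import SegLine


def toy_tiles(rng, n=24, sep=120):
    """Separable toy task: lesion tiles carry a dark center patch."""
    tiles = []
    for i in range(n):
        label = "lesion" if i % 2 else "normal"
        px = np.full((24, 24), 150, dtype=np.uint8)
        px += rng.integers(0, 10, size=px.shape, dtype=np.uint8)
        if label == "lesion":
            px[8:16, 8:16] = sep - 100
        tiles.append(ToothTile(pixels=px, source_id=f"t{i}",
                               left_line=SegLine(0, 0),
                               right_line=SegLine(23, 23),
                               threshold_T=85, label=label))
    return tiles


class TestSchedule:
    @pytest.mark.parametrize("epoch, expected", [
        (1, 1e-4), (5, 1e-4), (6, 2e-5), (10, 2e-5), (11, 4e-6), (50, 1e-4 * 0.2 ** 9),
    ])
    def test_closed_form(self, epoch, expected):
        assert learning_rate_schedule(epoch) == pytest.approx(expected, rel=1e-12)

    def test_general_form(self):
        for epoch in range(1, 30):
            got = learning_rate_schedule(epoch, 3e-3, 0.5, 4)
            assert got == pytest.approx(3e-3 * 0.5 ** ((epoch - 1) // 4))


class TestGradients:
    def test_numeric_gradient_check(self, rng):
        """Backprop through the default backbone matches finite differences."""
        cfg = TrainConfig(input_side=8, seed=0)
        model = build_model(cfg)
        x = rng.normal(scale=50.0, size=(3, 1, 8, 8))
        y = np.array([0, 1, 1])
        loss, gy = _softmax_xent(model.forward(x, train=True), y)
        model.backward(gy)
        for p in model.parameters()[:2]:       # first conv weight + bias
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            eps = 1e-5
            analytic = p.grad[idx]
            p.value[idx] += eps
            lp, _ = _softmax_xent(model.forward(x, train=True), y)
            p.value[idx] -= 2 * eps
            lm, _ = _softmax_xent(model.forward(x, train=True), y)
            p.value[idx] += eps
            numeric = (lp - lm) / (2 * eps)
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestTrainHarness:
    def test_log_shape_and_determinism(self, rng):
        tiles = toy_tiles(rng)
        ds = split(tiles, 0.7, seed=0)
        cfg = TrainConfig(max_epoch=2, input_side=24, seed=3,
                          mini_batch_size=8, validation_frequency=2)
        m1, log1 = train(ds, cfg)
        m2, log2 = train(ds, cfg)
        assert list(log1.columns) == LOG_COLUMNS
        assert (log1.epoch == log1.epoch.sort_values().values).all()
        assert log1.drop(columns="time_elapsed").equals(
            log2.drop(columns="time_elapsed"))
        assert log1.validation_accuracy.notna().iloc[0]
        assert log1.validation_accuracy.notna().iloc[-1]

    def test_single_class_split_raises(self, rng):
        tiles = toy_tiles(rng)
        ds = split(tiles, 0.7, seed=0)
        ds.split_assignment = ["train" if t.label == "lesion" else "val"
                               for t in ds.tiles]
        with pytest.raises(ValueError, match="single-class"):
            train(ds, TrainConfig(max_epoch=1, input_side=24))

    def test_empty_validation_split_raises(self, rng):
        tiles = toy_tiles(rng)
        ds = split(tiles, 0.7, seed=0)
        ds.split_assignment = ["train"] * len(ds.tiles)
        with pytest.raises(ValueError, match="empty val"):
            train(ds, TrainConfig(max_epoch=1, input_side=24))

    def test_save_load_roundtrip(self, rng, tmp_path):
        tiles = toy_tiles(rng)
        ds = split(tiles, 0.7, seed=0)
        cfg = TrainConfig(max_epoch=1, input_side=24, seed=1)
        model, _ = train(ds, cfg)
        save_model(model, cfg, tmp_path / "m.npz")
        clone = load_model(tmp_path / "m.npz")
        val = ds.subset("val")
        assert np.array_equal(predict(model, val), predict(clone, val))


class TestConfusionAndMetrics:
    def test_cell_sum_conserved_and_perfect_diagonal(self, rng):
        tiles = toy_tiles(rng, n=20)
        ds = split(tiles, 0.7, seed=0)
        cfg = TrainConfig(max_epoch=3, input_side=24, seed=2,
                          mini_batch_size=8)
        model, _ = train(ds, cfg)
        val = ds.subset("val")
        cm = evaluate(model, val)
        assert cm.total == len(val)

    def test_published_confusion_worked_example(self):
        """From the published percentage confusion matrix (predicted x
        actual: normal/normal 46.8, normal/lesion 4.3, lesion/normal 2.1,
        lesion/lesion 46.8) the lesion-positive metrics follow by formula."""
        cm = ConfusionMatrix(cells=np.array([[46.8, 4.3], [2.1, 46.8]]))
        rep = metrics_from_confusion(cm)
        assert round(rep.recall, 1) == 91.6          # TP / (TP + FN)
        assert round(rep.precision, 1) == 95.7       # TP / (TP + FP)
        assert round(rep.f1, 1) == 93.6
        assert rep.accuracy == pytest.approx(93.6, abs=0.05)

    def test_identity_matrix_all_100(self):
        rep = metrics_from_confusion(ConfusionMatrix(np.eye(2) * 10))
        assert (rep.accuracy, rep.recall, rep.precision, rep.f1) == \
            (100.0, 100.0, 100.0, 100.0)

    def test_zero_denominator_is_undefined_not_zero(self):
        # constant "normal" predictor: no predicted lesions
        rep = metrics_from_confusion(ConfusionMatrix(np.array([[8., 2.],
                                                               [0., 0.]])))
        assert rep.precision is None and rep.f1 is None
        assert rep.recall == 0.0

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(25):
            cells = rng.integers(1, 50, size=(2, 2)).astype(float)
            rep = metrics_from_confusion(ConfusionMatrix(cells))
            assert min(rep.precision, rep.recall) - 1e-9 <= rep.f1
            assert rep.f1 <= max(rep.precision, rep.recall) + 1e-9

    def test_accuracy_equals_trace_share(self, rng):
        cells = rng.integers(0, 100, size=(2, 2)).astype(float)
        cells[0, 0] += 1
        rep = metrics_from_confusion(ConfusionMatrix(cells))
        assert rep.accuracy == pytest.approx(
            100 * np.trace(cells) / cells.sum(), abs=1e-9)
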