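import numpy as np
import pytest

from panelforge import ffnn
from panelforge.ffnn import (
    CVSummary,
    DivergenceError,
    FFNNModel,
    NetworkArchitecture,
    TrainingConfig,
    TrainingError,
    cross_validate,
    encode_labels,
    forward,
    gradients,
    hidden_layer_size,
    initialize_model,
    predict_score,
    predict_scores,
    sse_loss,
    stratified_folds,
    train,
)
from panelforge.metrics import confusion_from_scores


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _separable_data(n_per_class=40, n_features=5, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    x_pos = rng.normal(gap, 1.0, size=(n_per_class, n_features))
    x_neg = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    x = np.vstack([x_pos, x_neg])
    labels = np.r_[np.ones(n_per_class, int), np.zeros(n_per_class, int)]
    return x, labels


class TestHiddenLayerSize:
    def test_five_input_two_output_gives_three(self):
        assert hidden_layer_size(5, 2) == 3

    def test_clamped_at_output_size(self):
        assert hidden_layer_size(2, 2) == 2

    def test_ten_inputs(self):
        assert hidden_layer_size(10, 2) == 6

    def test_rejects_input_smaller_than_output(self):
        with pytest.raises(ValueError):
            hidden_layer_size(1, 2)


class TestArchitecture:
    def test_output_must_be_two(self):
        with pytest.raises(ValueError):
            NetworkArchitecture(5, 3, n_output=3)

    def test_for_panel(self):
        arch = NetworkArchitecture.for_panel(5)
        assert (arch.n_input, arch.n_hidden, arch.n_output) == (5, 3, 2)


class TestForward:
    def _zero_model(self, n_in=3, n_hid=2):
        arch = NetworkArchitecture(n_in, n_hid)
        return FFNNModel(arch, np.zeros((n_hid, n_in)), np.zeros(n_hid),
                         np.zeros((2, n_hid)), np.zeros(2))

    def test_all_zero_weights_give_half(self):
        assert forward(self._zero_model(), [1.0, -2.0, 3.0]) == (0.5, 0.5)

    def test_hand_computed_unit_network(self):
        # 2-1-2 net, all weights 1, no biases, input (0,0):
        # hidden = sigmoid(0) = 0.5; each output = sigmoid(0.5)
        arch = NetworkArchitecture(2, 1)
        model = FFNNModel(arch, np.ones((1, 2)), np.zeros(1),
                          np.ones((2, 1)), np.zeros(2))
        expected = _sigmoid(_sigmoid(0.0))
        out = forward(model, [0.0, 0.0])
        assert out == pytest.approx((expected, expected), abs=1e-15)

    def test_outputs_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        arch = NetworkArchitecture(4, 3)
        model = initialize_model(arch, TrainingConfig(seed=1))
        for _ in range(20):
            c, h = forward(model, rng.normal(scale=100.0, size=4))
            assert 0.0 < c < 1.0 and 0.0 < h < 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            forward(self._zero_model(), [1.0])


class TestPredictScore:
    def test_score_arithmetic(self):
        # a model is not needed: check the convention via scores directly
        cm = confusion_from_scores([0.9 - 0.1], [1])
        assert cm.tp == 1

    def test_tie_predicts_control(self):
        cm = confusion_from_scores([0.5 - 0.5], [1])
        assert cm.fn == 1

    def test_threshold_equals_argmax(self):
        # equivalence oracle on random networks
        rng = np.random.default_rng(2)
        arch = NetworkArchitecture(3, 2)
        x = rng.normal(size=(50, 3))
        labels = np.r_[np.ones(25, int), np.zeros(25, int)]
        for seed in range(5):
            model = initialize_model(arch, TrainingConfig(seed=seed),
                                     np.random.default_rng(seed))
            scores = predict_scores(model, x)
            by_score = scores > 0
            outs = np.array([forward(model, row) for row in x])
            by_argmax = outs[:, 0] > outs[:, 1]
            assert np.array_equal(by_score, by_argmax)


class TestGradients:
    @pytest.mark.parametrize("n_input", range(2, 9))
    def test_finite_difference_oracle(self, n_input):
        rng = np.random.default_rng(n_input)
        arch = NetworkArchitecture(n_input, hidden_layer_size(n_input, 2))
        model = initialize_model(arch, TrainingConfig(seed=n_input), rng)
        x = rng.normal(size=(12, n_input))
        targets = encode_labels(rng.integers(0, 2, 12))
        grads = gradients(model, x, targets)

        h = 1e-5
        for name in ("w1", "b1", "w2", "b2"):
            param = getattr(model, name)
            numeric = np.zeros_like(param)
            it = np.nditer(param, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = param[idx]
                param[idx] = orig + h
                up = float(((targets - ffnn._forward_batch(model, x)[1]) ** 2).sum())
                param[idx] = orig - h
                down = float(((targets - ffnn._forward_batch(model, x)[1]) ** 2).sum())
                param[idx] = orig
                numeric[idx] = (up - down) / (2 * h)
            scale = np.maximum(np.abs(numeric), 1e-8)
            assert np.max(np.abs(grads[name] - numeric) / scale) < 1e-6


class TestTrain:
    def test_separable_data_high_accuracy(self):
        x, labels = _separable_data(seed=3)
        model = train(x, labels, NetworkArchitecture.for_panel(5),
                      TrainingConfig(learning_rate=0.05, max_epochs=300, seed=3))
        scores = predict_scores(model, x)
        acc = np.mean((scores > 0) == (labels == 1))
        assert acc >= 0.95

    def test_zero_learning_rate_keeps_weights(self):
        x, labels = _separable_data(n_per_class=10, seed=4)
        cfg = TrainingConfig(learning_rate=0.0, max_epochs=50, seed=4)
        init = initialize_model(NetworkArchitecture.for_panel(5), cfg)
        model = train(x, labels, NetworkArchitecture.for_panel(5), cfg, init=init)
        assert np.array_equal(model.w1, init.w1)
        assert np.array_equal(model.w2, init.w2)

    def test_single_class_rejected(self):
        x = np.zeros((5, 2))
        with pytest.raises(TrainingError):
            train(x, [1, 1, 1, 1, 1], NetworkArchitecture(2, 2), TrainingConfig())

    def test_loss_non_increasing_small_lr(self):
        x, labels = _separable_data(n_per_class=15, seed=5)
        model = train(x, labels, NetworkArchitecture.for_panel(5),
                      TrainingConfig(learning_rate=1e-3, max_epochs=200, seed=5))
        sse = np.array(model.sse_log)
        assert np.all(np.diff(sse) <= 1e-12)

    def test_determinism_bit_identical(self):
        x, labels = _separable_data(n_per_class=12, seed=6)
        cfg = TrainingConfig(learning_rate=0.05, max_epochs=80, seed=6)
        m1 = train(x, labels, NetworkArchitecture.for_panel(5), cfg)
        m2 = train(x, labels, NetworkArchitecture.for_panel(5), cfg)
        assert np.array_equal(m1.w1, m2.w1) and np.array_equal(m1.w2, m2.w2)
        assert m1.sse_log == m2.sse_log

    def test_final_sse_recomputable(self):
        x, labels = _separable_data(n_per_class=10, seed=7)
        model = train(x, labels, NetworkArchitecture.for_panel(5),
                      TrainingConfig(learning_rate=0.05, max_epochs=60, seed=7))
        assert model.final_sse == pytest.approx(
            sse_loss(model, x, encode_labels(labels)), abs=1e-12)

    def test_standardization_statistics_stored(self):
        x, labels = _separable_data(n_per_class=10, seed=8)
        model = train(x, labels, NetworkArchitecture.for_panel(5),
                      TrainingConfig(seed=8))
        assert np.allclose(model.x_mean, x.mean(axis=0))


class TestStratifiedFolds:
    def test_partition_property(self):
        labels = np.r_[np.ones(13, int), np.zeros(17, int)]
        folds = stratified_folds(labels, 5, np.random.default_rng(0))
        combined = np.sort(np.concatenate(folds))
        assert np.array_equal(combined, np.arange(30))

    def test_small_class_rejected(self):
        with pytest.raises(TrainingError):
            stratified_folds([1, 1, 0, 0, 0, 0, 0], 3, np.random.default_rng(0))


class TestCrossValidate:
    def test_separable_perfect_auc(self):
        x, labels = _separable_data(n_per_class=10, gap=6.0, seed=9)
        cv = cross_validate(x, labels, NetworkArchitecture.for_panel(5),
                            TrainingConfig(learning_rate=0.05, max_epochs=60, seed=9),
                            k=10)
        assert cv.best_mean_auc == 1.0

    def test_permuted_labels_near_chance(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x, labels = _separable_data(n_per_class=20, gap=4.0, seed=seed)
            permuted = rng.permutation(labels)
            if len(np.unique(permuted)) < 2:
                continue
            cv = cross_validate(x, permuted, NetworkArchitecture.for_panel(5),
                                TrainingConfig(learning_rate=0.05, max_epochs=40,
                                               seed=seed), k=5)
            aucs.append(cv.mean_auc)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_determinism(self):
        x, labels = _separable_data(n_per_class=10, seed=10)
        cfg = TrainingConfig(learning_rate=0.05, max_epochs=30, seed=10)
        cv1 = cross_validate(x, labels, NetworkArchitecture.for_panel(5), cfg)
        cv2 = cross_validate(x, labels, NetworkArchitecture.for_panel(5), cfg)
        assert np.array_equal(cv1.fold_auc_curves, cv2.fold_auc_curves)
        assert cv1.best_epoch == cv2.best_epoch
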