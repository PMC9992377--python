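"""The convolutional classifier: structure, gradients, reproducibility."""

import numpy as np
import pytest

import groupplv as gp
from groupplv import model as mm
from groupplv.model import _softmax


def test_layer_sequence_matches_design():
    m = mm.build_model()
    assert m.layer_names == [
        "conv", "batchnorm", "maxpool", "dropout",
        "conv", "batchnorm", "maxpool", "dropout",
        "flatten", "dense", "dense",
    ]


def test_parameter_count_matches_hand_tally():
    """Layer-by-layer arithmetic for the default 32x32 config."""
    cfg = mm.ModelConfig()
    conv1 = cfg.conv1_filters * (1 * cfg.kernel_size**2) + cfg.conv1_filters
    bn1 = 2 * cfg.conv1_filters
    conv2 = cfg.conv2_filters * (cfg.conv1_filters * cfg.kernel_size**2) \
        + cfg.conv2_filters
    bn2 = 2 * cfg.conv2_filters
    flat = (32 // 4) * (32 // 4) * cfg.conv2_filters  # two 2x2 pools
    dense1 = flat * cfg.dense_units + cfg.dense_units
    dense2 = cfg.dense_units * cfg.n_classes + cfg.n_classes
    expected = conv1 + bn1 + conv2 + bn2 + dense1 + dense2
    assert mm.build_model(cfg).n_parameters == expected


def test_config_validation():
    with pytest.raises(ValueError):
        mm.ModelConfig(dropout=1.0)
    with pytest.raises(ValueError):
        mm.ModelConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        mm.ModelConfig(kernel_size=4)
    with pytest.raises(ValueError):
        mm.SplitSpec(test_size=0.0)


def test_softmax_probabilities_sum_to_one(rng):
    m = mm.build_model()
    x = rng.random((7, 32, 32))
    prob = m.predict_proba(x)
    assert prob.shape == (7, 2)
    np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-6)
    assert np.all((prob >= 0) & (prob <= 1))


def test_duplicate_inputs_get_identical_predictions(rng):
    m = mm.build_model()
    x = rng.random((1, 32, 32))
    prob = m.predict_proba(np.concatenate([x, x, x]))
    np.testing.assert_array_equal(prob[0], prob[1])
    np.testing.assert_array_equal(prob[0], prob[2])


def test_input_shape_mismatch_errors(rng):
    with pytest.raises(ValueError):
        mm.build_model().predict_proba(rng.random((2, 16, 16)))


def test_numeric_gradient_check(rng):
    """Backprop through conv/batch-norm/pool/dense matches central
    differences on a tiny float64 network (dropout disabled)."""
    cfg = mm.ModelConfig(input_shape=(8, 8), conv1_filters=3, conv2_filters=4,
                         dense_units=6, dropout=0.0, seed=1, dtype="float64")
    m = mm.build_model(cfg)
    x = rng.random((4, 1, 8, 8))
    y = np.array([0, 1, 1, 0])

    def loss_only():
        probs = _softmax(m._forward(x, True))
        return -np.mean(np.log(probs[np.arange(4), y] + 1e-12))

    m.loss_and_grad(x, y, train=True)
    checked = 0
    for li, lay in enumerate(m.layers):
        for k, p in lay.params.items():
            if lay.name == "conv" and k == "b":
                continue  # absorbed by the following batch-norm: gradient ~0
            g = lay.grads[k]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-6
            p[idx] += eps
            lp = loss_only()
            p[idx] -= 2 * eps
            lm = loss_only()
            p[idx] += eps
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-8), f"{li}:{k}"
            checked += 1
    assert checked >= 8


def _toy_separable(n=80, seed=0):
    """Two classes of 32x32 'matrices' with different block intensity."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = rng.uniform(0.1, 0.4, (n, 32, 32))
    x[y == 1, 8:24, 8:24] += 0.5
    return np.clip(x, 0, 1), y


class TestTraining:
    def test_fixed_seed_reproduces_history_and_predictions(self):
        x, y = _toy_separable()
        runs = []
        for _ in range(2):
            m = mm.train(mm.build_model(mm.ModelConfig(epochs=2, seed=3)),
                         (x, y), mm.SplitSpec(seed=3))
            runs.append((m.history, m.predict_proba(x)))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_loss_decreases_on_separable_data(self):
        x, y = _toy_separable()
        m = mm.train(mm.build_model(mm.ModelConfig(epochs=3, seed=0)),
                     (x, y), mm.SplitSpec(seed=0))
        losses = m.history["loss"]
        assert len(losses) == 3
        assert losses[1] <= losses[0] and losses[2] <= losses[1]

    def test_high_accuracy_on_separable_toy(self):
        x, y = _toy_separable(n=120, seed=1)
        m = mm.train(mm.build_model(mm.ModelConfig(epochs=12, seed=0)),
                     (x, y), mm.SplitSpec(seed=0))
        acc = np.mean(m.predict(x[m.test_indices]) == y[m.test_indices])
        assert acc >= 0.9

    def test_single_class_rejected(self):
        x, _ = _toy_separable()
        with pytest.raises(ValueError):
            mm.train(mm.build_model(), (x, np.zeros(len(x), dtype=int)))

    def test_inputs_outside_unit_interval_rejected(self):
        x, y = _toy_separable()
        with pytest.raises(ValueError):
            mm.train(mm.build_model(), (x * 3.0, y))

    def test_test_partition_is_disjoint_and_stratified(self):
        x, y = _toy_separable(n=100)
        m = mm.train(mm.build_model(mm.ModelConfig(epochs=1, seed=0)),
                     (x, y), mm.SplitSpec(test_size=0.2, seed=0))
        assert len(m.test_indices) == 20
        assert np.bincount(y[m.test_indices]).tolist() == [10, 10]


def test_save_load_round_trip(tmp_path):
    x, y = _toy_separable()
    m = mm.train(mm.build_model(mm.ModelConfig(epochs=1, seed=2)),
                 (x, y), mm.SplitSpec(seed=2))
    path = m.save(tmp_path / "cnn")
    back = mm.CNNClassifier.load(path)
    np.testing.assert_array_equal(back.predict_proba(x), m.predict_proba(x))
    assert back.history == m.history


def test_predict_accepts_dataset_and_matrix_lists(tiny_corpus):
    cfg, corpus = tiny_corpus
    recs = [r for recs in corpus for r in recs]
    mats = gp.extract_individual_matrices(recs, "gamma")
    m = mm.build_model()
    prob = mm.predict(m, mats[:3])
    assert prob.shape == (3, 2)
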