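import numpy as np
import pytest

from fetalarr import cnn
from fetalarr.types import (
    ARRHYTHMIA_SEG,
    MODERATE_SEG,
    NORMAL_SEG,
    Segment,
)


def _segment(samples, sid="s", subject_class="healthy"):
    return Segment(subject_id=sid, start_time=0.0, samples=samples,
                   contained_rris=np.empty(0), subject_class=subject_class)


def _toy_dataset(n_per_class=40, seed=0):
    """Separable toy: impulse trains at 400 ms vs 600 ms spacing."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for cls, spacing in ((0, 200), (1, 300)):  # samples at 500 Hz
        for _ in range(n_per_class):
            x = rng.normal(0, 0.05, 1500)
            x[rng.integers(0, spacing) :: spacing] += 1.0
            X.append(x)
            y.append(cls)
    return np.asarray(X), np.asarray(y)


def test_normalize_segments_zero_mean_unit_sd():
    X = np.random.default_rng(0).normal(3.0, 2.0, (5, 100))
    Z = cnn.normalize_segments(X)
    np.testing.assert_allclose(Z.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(Z.std(axis=1), 1.0, atol=1e-12)
    np.testing.assert_array_equal(cnn.normalize_segments(np.ones((2, 10))), 0.0)


def test_build_training_set_drops_moderate_in_binary():
    segs = [_segment(np.zeros(1500)) for _ in range(3)]
    labels = [NORMAL_SEG, MODERATE_SEG, ARRHYTHMIA_SEG]
    X, y, classes = cnn.build_training_set(segs, labels, mode="binary")
    assert X.shape == (2, 1500)
    assert list(y) == [0, 1]
    assert classes == cnn.BINARY_CLASSES


def test_build_training_set_requires_all_classes():
    segs = [_segment(np.zeros(1500)) for _ in range(2)]
    with pytest.raises(ValueError):
        cnn.build_training_set(segs, [NORMAL_SEG, NORMAL_SEG], mode="binary")
    with pytest.raises(ValueError):
        cnn.build_training_set(segs, [NORMAL_SEG, ARRHYTHMIA_SEG], mode="ternary")


def test_training_is_deterministic():
    X, y = _toy_dataset(n_per_class=10)
    cfg = cnn.CNNConfig(epochs=2, seed=5)
    m1 = cnn.train(cfg, X, y)
    m2 = cnn.train(cfg, X, y)
    for name in m1.params:
        np.testing.assert_array_equal(m1.params[name], m2.params[name])
    assert m1.history == m2.history


def test_learns_separable_classes():
    X, y = _toy_dataset(n_per_class=80)
    model = cnn.train(cnn.CNNConfig(epochs=20, seed=0), X, y)
    acc = float(np.mean(model.predict_proba(X).argmax(axis=1) == y))
    assert acc >= 0.95


def test_predict_proba_rows_sum_to_one():
    X, y = _toy_dataset(n_per_class=5)
    model = cnn.train(cnn.CNNConfig(epochs=1, seed=0), X, y)
    probs = model.predict_proba(X)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert probs.min() >= 0.0


def test_predict_wraps_segments_with_class_names():
    X, y = _toy_dataset(n_per_class=5)
    model = cnn.train(cnn.CNNConfig(epochs=1, seed=0), X, y)
    preds = cnn.predict(model, [_segment(X[0]), _segment(X[-1])])
    assert all(p.predicted in cnn.BINARY_CLASSES for p in preds)
    assert all(abs(sum(p.scores.values()) - 1.0) < 1e-6 for p in preds)


def test_wrong_input_length_rejected():
    model = cnn.CNN1D(cnn.CNNConfig())
    with pytest.raises(ValueError):
        model.predict_proba(np.zeros((1, 1000)))
    with pytest.raises(ValueError):
        model.fit(np.zeros((4, 1000)), np.array([0, 1, 0, 1]))


def test_single_class_targets_rejected():
    model = cnn.CNN1D(cnn.CNNConfig(epochs=1))
    with pytest.raises(ValueError):
        model.fit(np.zeros((4, 1500)), np.zeros(4, dtype=int))


def test_save_load_roundtrip(tmp_path):
    X, y = _toy_dataset(n_per_class=5)
    model = cnn.train(cnn.CNNConfig(epochs=1, seed=0), X, y)
    model.save(tmp_path / "model")
    back = cnn.CNN1D.load(tmp_path / "model")
    np.testing.assert_array_equal(model.predict_proba(X), back.predict_proba(X))
    assert back.config == model.config


def test_training_log_csv(tmp_path):
    X, y = _toy_dataset(n_per_class=5)
    model = cnn.train(cnn.CNNConfig(epochs=3, seed=0), X, y)
    cnn.save_training_log(model, tmp_path / "log.csv")
    lines = (tmp_path / "log.csv").read_text().strip().splitlines()
    assert lines[0] == "epoch,loss,accuracy"
    assert len(lines) == 4


def test_config_validation():
    with pytest.raises(ValueError):
        cnn.CNNConfig(n_classes=4)
    with pytest.raises(ValueError):
        cnn.CNNConfig(filters=(8, 16, 32))
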