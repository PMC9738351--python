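"""Architecture arithmetic, network instantiation, training behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emdnet.cnn import (
    EMDNetClassifier,
    LayerSpec,
    ModelSpec,
    ShapeError,
    TrainConfig,
    build_model,
    count_parameters,
    default_model_spec,
    load_checkpoint,
    predict,
    save_checkpoint,
    shape_trace,
    train,
)


def brute_force_window_count(w: int, k: int, stride: int, padding: str) -> int:
    """Independent oracle: enumerate window start positions explicitly."""
    if padding == "same":
        out = math.ceil(w / stride)
        total_pad = max((out - 1) * stride + k - w, 0)
        w = w + total_pad
    starts = [s for s in range(0, w - k + 1, stride)]
    return len(starts)


@st.composite
def small_specs(draw):
    """Random small conv/pool/dense stacks over modest input extents."""
    h = draw(st.integers(1, 4))
    w = draw(st.integers(16, 64))
    c = draw(st.integers(1, 4))
    layers = []
    n_blocks = draw(st.integers(1, 3))
    for _ in range(n_blocks):
        kind = draw(st.sampled_from(["conv2d", "maxpool2d"]))
        k = draw(st.integers(1, 5))
        stride = draw(st.integers(1, 3))
        padding = draw(st.sampled_from(["same", "valid"]))
        if kind == "conv2d":
            layers.append(LayerSpec("conv2d", kernel=(1, k), stride=(1, stride),
                                    padding=padding, units=draw(st.integers(1, 8)),
                                    activation="relu"))
        else:
            layers.append(LayerSpec("maxpool2d", kernel=(1, k), stride=(1, stride),
                                    padding=padding))
    layers.append(LayerSpec("flatten"))
    layers.append(LayerSpec("dense", units=draw(st.integers(1, 8)), activation="relu"))
    layers.append(LayerSpec("dense", units=3, activation="softmax"))
    return ModelSpec(layers=tuple(layers), input_shape=(h, w, c))


class TestShapeTrace:
    def test_default_spec_shape_chain(self):
        trace = dict(shape_trace(default_model_spec()))
        assert trace["0:conv2d"] == (19, 640, 64)
        assert trace["1:maxpool2d"] == (19, 320, 64)
        assert trace["2:conv2d"] == (19, 160, 32)
        assert trace["3:maxpool2d"] == (19, 80, 32)
        assert trace["4:flatten"] == (48640,)

    def test_inconsistent_kernel_names_layer(self):
        spec = ModelSpec(layers=(
            LayerSpec("maxpool2d", kernel=(1, 50), stride=(1, 1), padding="valid"),
        ), input_shape=(2, 10, 1))
        with pytest.raises(ShapeError, match="0:maxpool2d"):
            shape_trace(spec)

    @given(small_specs())
    @settings(max_examples=60, deadline=None)
    def test_width_propagation_matches_window_enumeration(self, spec):
        shape = spec.input_shape
        try:
            trace = shape_trace(spec)
        except ShapeError:
            return  # kernel wider than input under 'valid': legitimately rejected
        w = shape[1]
        for layer, (_, out_shape) in zip(spec.layers, trace[1:]):
            if layer.kind in ("conv2d", "maxpool2d"):
                expected = brute_force_window_count(
                    w, layer.kernel[1], layer.stride[1], layer.padding)
                assert out_shape[1] == expected
                w = out_shape[1]


class TestCountParameters:
    def test_published_per_layer_counts(self):
        counts, total = count_parameters(default_model_spec())
        d = dict(counts)
        assert d["0:conv2d"] == 1216
        assert d["2:conv2d"] == 6176
        assert d["5:dense"] == 6_226_048
        assert d["6:dense"] == 4128
        assert d["8:dense"] == 528
        assert d["9:dense"] == 51
        assert total == 6_238_147

    @given(small_specs())
    @settings(max_examples=40, deadline=None)
    def test_closed_form_matches_instantiated_network(self, spec):
        try:
            counts, total = count_parameters(spec)
        except ShapeError:
            return
        net = build_model(spec, seed=0)
        per_layer = [l.n_params() for l in net.layers]
        assert per_layer == [n for _, n in counts]
        assert net.n_params() == total


class TestBuildModel:
    def test_same_seed_identical_weights(self):
        a = build_model(default_model_spec(), 42)
        b = build_model(default_model_spec(), 42)
        for la, lb in zip(a.layers, b.layers):
            for k in la.params:
                assert np.array_equal(la.params[k], lb.params[k])

    def test_forward_is_a_probability_vector(self, rng):
        net = build_model(default_model_spec(), 0)
        x = rng.standard_normal((1, 19, 1280, 3)).astype(np.float32)
        p = net.forward(x)
        assert p.shape == (1, 3)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-6


@pytest.fixture(scope="module")
def tiny_spec():
    """A scaled-down stack with the same layer kinds, for fast training tests."""
    return ModelSpec(layers=(
        LayerSpec("conv2d", kernel=(1, 6), stride=(1, 4), padding="same",
                  units=8, activation="relu"),
        LayerSpec("maxpool2d", kernel=(1, 4), stride=(1, 4), padding="valid"),
        LayerSpec("flatten"),
        LayerSpec("dense", units=16, activation="relu"),
        LayerSpec("dropout", rate=0.3),
        LayerSpec("dense", units=3, activation="softmax"),
    ), input_shape=(19, 1280, 3))


def _separable_tensors(rng, n_per_class=10):
    t = np.arange(1280) / 256.0
    X, y = [], []
    for c, f in enumerate((16.0, 10.0, 4.0)):
        tone = np.sin(2 * np.pi * f * t)
        for _ in range(n_per_class):
            x = 0.3 * rng.standard_normal((19, 1280, 3))
            x[:, :, 0] += tone
            X.append(x)
            y.append(c)
    return np.array(X, dtype=np.float32), np.array(y)


class TestTraining:
    def test_zero_learning_rate_freezes_loss(self, rng, tiny_spec):
        X, y = _separable_tensors(rng, n_per_class=2)
        onehot = np.eye(3, dtype=np.float32)[y]
        net = build_model(tiny_spec, 0)
        hist = train(net, X, onehot,
                     TrainConfig(learning_rate=0.0, epochs=3, seed=0))
        assert max(hist) - min(hist) < 1e-12

    def test_initial_loss_near_log3_with_permuted_labels(self, rng, tiny_spec):
        X, y = _separable_tensors(rng, n_per_class=4)
        y = rng.permutation(y)
        onehot = np.eye(3, dtype=np.float32)[y]
        net = build_model(tiny_spec, 0)
        hist = train(net, X, onehot,
                     TrainConfig(learning_rate=1e-4, epochs=1, seed=0))
        assert hist[0] == pytest.approx(np.log(3), rel=0.20)

    def test_missing_class_is_rejected(self, rng, tiny_spec):
        X, y = _separable_tensors(rng, n_per_class=2)
        onehot = np.eye(3, dtype=np.float32)[y]
        onehot = onehot[y != 2]
        with pytest.raises(ValueError, match="absent"):
            train(build_model(tiny_spec, 0), X[y != 2], onehot,
                  TrainConfig(epochs=1))

    def test_overfits_separable_data_to_full_accuracy(self, rng):
        # capacity sanity on the full-size architecture
        X, y = _separable_tensors(rng, n_per_class=10)
        clf = EMDNetClassifier(learning_rate=1e-3, epochs=20,
                               normalize=True, random_state=0)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_same_seed_reproduces_loss_history(self, rng, tiny_spec):
        X, y = _separable_tensors(rng, n_per_class=3)
        onehot = np.eye(3, dtype=np.float32)[y]
        h1 = train(build_model(tiny_spec, 7), X, onehot,
                   TrainConfig(learning_rate=1e-3, epochs=2, seed=7))
        h2 = train(build_model(tiny_spec, 7), X, onehot,
                   TrainConfig(learning_rate=1e-3, epochs=2, seed=7))
        assert h1 == h2


class TestPredict:
    def test_batch_equals_concatenated_singles(self, rng, tiny_spec):
        net = build_model(tiny_spec, 0)
        X = rng.standard_normal((5, 19, 1280, 3)).astype(np.float32)
        batch_probs, batch_labels = predict(net, X)
        singles = np.concatenate([predict(net, X[i : i + 1])[0] for i in range(5)])
        assert batch_probs.shape == (5, 3)
        assert np.allclose(batch_probs, singles, atol=1e-5)

    def test_wrong_shape_rejected(self, tiny_spec):
        net = build_model(tiny_spec, 0)
        with pytest.raises(ShapeError):
            predict(net, np.zeros((2, 19, 640, 3), dtype=np.float32))

    def test_probabilities_sum_to_one(self, rng, tiny_spec):
        net = build_model(tiny_spec, 0)
        X = rng.standard_normal((4, 19, 1280, 3)).astype(np.float32)
        probs, _ = predict(net, X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestEstimatorAndCheckpoint:
    def test_sklearn_params_round_trip(self):
        clf = EMDNetClassifier(epochs=3, learning_rate=1e-3)
        params = clf.get_params()
        assert params["epochs"] == 3
        clone = EMDNetClassifier(**params)
        assert clone.get_params() == params

    def test_checkpoint_round_trip_preserves_predictions(self, rng, tiny_spec, tmp_path):
        X, y = _separable_tensors(rng, n_per_class=2)
        clf = EMDNetClassifier(model_spec=tiny_spec, learning_rate=1e-3,
                               epochs=2, normalize=True, random_state=0)
        clf.fit(X, y)
        save_checkpoint(clf, tmp_path / "model")
        back = load_checkpoint(tmp_path / "model")
        assert np.allclose(clf.predict_proba(X), back.predict_proba(X), atol=1e-6)
        import json
        sidecar = json.loads((tmp_path / "model.json").read_text())
        assert sidecar["spec_hash"] == clf.spec_hash_
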