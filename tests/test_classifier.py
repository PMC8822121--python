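"""ConvLSTM classifier: gradients, construction, weights, training, streaming."""

import numpy as np
import pytest

from gazegrasp.classifier import (
    ClassMap,
    ModelSpec,
    TrainConfig,
    build_model,
    compute_class_weights,
    load_model,
    predict_stream,
    save_model,
    train,
)
from gazegrasp.convlstm import ConvLSTMNet
from gazegrasp.emg import WindowSpec, tensorize
from gazegrasp.protocol import GRASPS, miniature_pairing
from gazegrasp.synthetic import SynthConfig, default_signatures, synthesize_emg_segment


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """The analytic BPTT gradient agrees with central differences."""
        rng = np.random.default_rng(0)
        net = ConvLSTMNet(n_filters=3, kernel_w=3, dense_units=(5, 4), n_classes=3,
                          n_subseq=3, width=6, channels=2, dropout1=0.0, dropout2=0.0,
                          seed=1, dtype=np.float64)
        X = rng.normal(size=(3, 3, 1, 6, 2))
        y = np.array([0, 1, 2])
        w = np.array([1.0, 0.7, 1.3])
        _, grads, _ = net.loss_and_grads(X, y, w, train=False)
        eps = 1e-6
        check_rng = np.random.default_rng(7)
        for name, p in net.params.items():
            flat = p.reshape(-1)
            picks = check_rng.choice(flat.size, size=min(25, flat.size), replace=False)
            for j in picks:
                orig = flat[j]
                flat[j] = orig + eps
                lp, _, _ = net.loss_and_grads(X, y, w, train=False)
                flat[j] = orig - eps
                lm, _, _ = net.loss_and_grads(X, y, w, train=False)
                flat[j] = orig
                gnum = (lp - lm) / (2 * eps)
                gana = grads[name].reshape(-1)[j]
                assert gnum == pytest.approx(gana, rel=1e-4, abs=1e-8), name


class TestConstruction:
    def test_full_architecture_emits_11_class_posteriors(self):
        model = build_model(ModelSpec(), seed=0)
        X = np.random.default_rng(0).normal(size=(4, 10, 1, 20, 12))
        probs = model.predict_proba(X)
        assert probs.shape == (4, 11)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_same_seed_identical_initial_parameters(self):
        spec = ModelSpec(convlstm_filters=8)
        a = build_model(spec, seed=11)
        b = build_model(spec, seed=11)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])
        c = build_model(spec, seed=12)
        assert any(not np.array_equal(a.params[k], c.params[k]) for k in a.params)

    def test_kernel_height_must_be_one(self):
        with pytest.raises(ValueError, match="height"):
            ModelSpec(kernel=(2, 3))

    def test_checkpoint_roundtrip(self, tmp_path):
        model = build_model(ModelSpec(convlstm_filters=4, output_units=3), seed=0)
        X = np.random.default_rng(1).normal(size=(3, 10, 1, 20, 12))
        save_model(model, tmp_path / "ckpt.npz")
        back = load_model(tmp_path / "ckpt.npz")
        assert np.array_equal(model.predict_proba(X), back.predict_proba(X))


class TestClassWeights:
    def test_uniform_counts_give_unit_weights(self):
        labels = np.repeat(np.arange(5), 40)
        w = compute_class_weights(labels, 5)
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_rest_twice_as_frequent_gets_half_weight(self):
        labels = np.array([0] * 200 + [1] * 100 + [2] * 100)
        w = compute_class_weights(labels, 3)
        assert w[0] == pytest.approx(w[1] / 2)
        assert w[1] == pytest.approx(w[2])

    def test_duplication_invariance(self):
        labels = np.array([0] * 50 + [1] * 30 + [2] * 20)
        w1 = compute_class_weights(labels, 3)
        w2 = compute_class_weights(np.tile(labels, 2), 3)
        assert w1 == w2

    def test_absent_class_raises_listing_it(self):
        with pytest.raises(ValueError, match=r"\[2\]"):
            compute_class_weights(np.array([0, 0, 1, 1]), 3)


class TestClassMap:
    def test_full_taxonomy_is_eleven_classes(self):
        cm = ClassMap(GRASPS)
        assert cm.n_classes == 11
        assert cm.index_of(0) == 0
        assert [cm.grasp_id_of(i) for i in range(11)] == list(range(11))

    def test_reduced_taxonomy(self):
        cm = ClassMap.from_pairing(miniature_pairing())
        assert cm.n_classes == 3
        assert cm.index_of(0) == 0
        assert cm.index_of(1) == 1  # medium wrap
        assert cm.index_of(4) == 2  # tripod grasp
        with pytest.raises(ValueError):
            cm.encode_labels(np.array([7]))


def _separable_dataset(n_per_class=30, noise_sd=0.0, seed=0):
    """Windows from noise-free (or noisy) synthetic segments, no scaler."""
    from gazegrasp.emg import window_segment

    cfg = SynthConfig(seed=seed, noise_sd=noise_sd)
    sigs = default_signatures(10)
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls, grasp in enumerate([GRASPS[0], GRASPS[3]], start=1):
        for _ in range(n_per_class):
            signal, labels = synthesize_emg_segment(
                grasp, (0.3, 0.5, 0.3), cfg, rng, sigs[grasp.id - 1]
            )
            w, wl = window_segment(np.abs(signal), labels)
            xs.append(w)
            ys.append(np.where(wl == grasp.id, cls, 0))
    X = tensorize(np.concatenate(xs).astype(np.float32))
    y = np.concatenate(ys)
    return X, y


class TestTraining:
    def test_separable_noise_free_data_reaches_full_validation_accuracy(self):
        X, y = _separable_dataset(n_per_class=20, noise_sd=0.0)
        n = len(y)
        idx = np.random.default_rng(0).permutation(n)
        cut = int(0.8 * n)
        model = build_model(ModelSpec(convlstm_filters=8, output_units=3), seed=0)
        cfg = TrainConfig(epochs=10, class_weights=compute_class_weights(y, 3), seed=0)
        hist = train(model, X[idx[:cut]], y[idx[:cut]], X[idx[cut:]], y[idx[cut:]], cfg)
        assert hist["val_acc"].max() == 1.0

    def test_constant_input_accuracy_matches_majority_rate(self):
        rng = np.random.default_rng(0)
        X = np.ones((300, 10, 1, 20, 12), dtype=np.float32)
        y = rng.choice(3, size=300, p=[0.6, 0.25, 0.15])
        model = build_model(ModelSpec(convlstm_filters=4, output_units=3), seed=0)
        hist = train(model, X, y, X[:60], y[:60], TrainConfig(epochs=5, seed=0))
        majority = np.bincount(y[:60]).max() / 60
        assert hist["val_acc"].iloc[-1] == pytest.approx(majority, abs=0.05)

    def test_best_snapshot_at_least_final_epoch(self):
        X, y = _separable_dataset(n_per_class=10, noise_sd=0.2)
        model = build_model(ModelSpec(convlstm_filters=4, output_units=3), seed=1)
        cfg = TrainConfig(epochs=4, class_weights=compute_class_weights(y, 3), seed=1)
        hist = train(model, X, y, X[:50], y[:50], cfg)
        best = hist["val_acc"].max()
        assert best >= hist["val_acc"].iloc[-1]
        # the model carries the best snapshot
        acc = (model.predict_proba(X[:50]).argmax(axis=1) == y[:50]).mean()
        assert acc == pytest.approx(best, abs=1e-9)


@pytest.fixture(scope="module")
def small_model():
    return build_model(ModelSpec(convlstm_filters=4, output_units=3), seed=0)


class TestStreaming:

    @pytest.mark.parametrize("length,expected", [(200, 1), (400, 11), (219, 1), (1000, 41)])
    def test_prediction_count(self, small_model, length, expected):
        x = np.random.default_rng(0).normal(size=(length, 12)).astype(np.float32)
        stream = predict_stream(small_model, x)
        assert len(stream) == expected
        assert stream.t[0] == 200
        assert np.all(np.diff(stream.t) == 20)

    def test_short_stream_is_empty(self, small_model):
        stream = predict_stream(small_model, np.zeros((150, 12), dtype=np.float32))
        assert len(stream) == 0

    def test_posteriors_normalized(self, small_model):
        x = np.random.default_rng(1).normal(size=(600, 12)).astype(np.float32)
        stream = predict_stream(small_model, x)
        assert np.allclose(stream.p.sum(axis=1), 1.0, atol=1e-6)

    def test_stream_equals_batch_on_extracted_windows(self, small_model):
        x = np.random.default_rng(2).normal(size=(800, 12)).astype(np.float32)
        stream = predict_stream(small_model, x)
        spec = WindowSpec()
        windows = np.stack([x[t - 200 : t] for t in stream.t])
        batch = small_model.predict_proba(tensorize(windows, spec))
        assert np.array_equal(stream.p, batch)

    def test_t_offset_shifts_reported_clock(self, small_model):
        x = np.random.default_rng(3).normal(size=(400, 12)).astype(np.float32)
        a = predict_stream(small_model, x, t_offset=0)
        b = predict_stream(small_model, x, t_offset=5000)
        assert np.array_equal(b.t, a.t + 5000)
        assert np.array_equal(a.p, b.p)
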