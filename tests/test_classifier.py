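import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from choroidseg.classifier import (
    Adam,
    Hyper,
    _focal_grad_logits,
    focal_loss,
    load_checkpoint,
    objective,
    save_checkpoint,
    train,
)
from choroidseg.nn import ArchConfig, PatchCNN, softmax


def toy_stripe_set(n, seed, pos_frac=0.5):
    """Separable toy task: positives carry a bright horizontal stripe through
    the patch center, negatives are flat noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.3, 0.1, size=(n, 32, 32)).astype(np.float32)
    y = (rng.random(n) < pos_frac).astype(int)
    X[y == 1, 14:18, :] += 0.5
    return np.clip(X, 0, 1), y


class TestFocalLoss:
    def test_perfectly_classified_positive_has_near_zero_loss(self):
        assert focal_loss(1 - 1e-7, 1, alpha=0.9, gamma=2.0) == pytest.approx(0.0, abs=1e-6)

    def test_uncertain_positive_value(self):
        expected = 0.9 * 0.25 * np.log(2.0)
        assert focal_loss(0.5, 1, alpha=0.9, gamma=2.0) == pytest.approx(expected, abs=1e-12)

    def test_reduces_to_half_cross_entropy_when_unweighted(self):
        p = np.linspace(0.01, 0.99, 100)
        for l in (0, 1):
            fl = focal_loss(p, np.full(100, l), alpha=0.5, gamma=0.0)
            ce = -(l * np.log(p) + (1 - l) * np.log(1 - p))
            assert np.max(np.abs(fl - 0.5 * ce)) < 1e-10

    @settings(max_examples=100, deadline=None)
    @given(
        p=st.floats(0.001, 0.999),
        alpha=st.floats(0.05, 0.95),
        gamma=st.floats(0.0, 5.0),
    )
    def test_nonnegative(self, p, alpha, gamma):
        assert focal_loss(p, 1, alpha, gamma) >= 0.0
        assert focal_loss(p, 0, alpha, gamma) >= 0.0

    def test_monotone_in_p(self):
        p = np.linspace(0.01, 0.99, 200)
        pos = focal_loss(p, np.ones(200), 0.9, 2.0)
        neg = focal_loss(p, np.zeros(200), 0.9, 2.0)
        assert np.all(np.diff(pos) < 0)  # more confident positive -> less loss
        assert np.all(np.diff(neg) > 0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(1.2, 1)
        with pytest.raises(ValueError):
            focal_loss(np.nan, 0)


class TestNetwork:
    def test_layer_output_shapes_match_architecture(self):
        net = PatchCNN(ArchConfig(width_scale=1.0), seed=0)
        x = np.random.default_rng(0).random((1, 32, 32)).astype(np.float32)[..., None]
        shapes = []
        for layer in net.layers:
            x = layer.forward(x)
            shapes.append(x.shape[1:])
        assert shapes[0] == (32, 32, 128)   # conv1
        assert shapes[3] == (32, 32, 64)    # conv2
        assert shapes[6] == (32, 32, 32)    # conv3
        assert shapes[9] == (32 * 32 * 32,)  # flatten
        assert shapes[10] == (4096,)
        assert shapes[12] == (1024,)
        assert shapes[14] == (2,)

    def test_equal_logits_give_half_probability(self):
        net = PatchCNN(ArchConfig(width_scale=1 / 16), seed=0)
        last = net.layers[-1]
        last.params["W"][:] = 0.0
        last.params["b"][:] = 0.0
        p = net.predict_proba(np.random.default_rng(1).random((3, 32, 32)))
        assert np.allclose(p, 0.5)

    def test_forward_deterministic_and_batch_invariant(self):
        net = PatchCNN(ArchConfig(width_scale=1 / 16), seed=0)
        X = np.random.default_rng(2).random((7, 32, 32)).astype(np.float32)
        p1 = net.predict_proba(X, batch_size=7)
        p2 = net.predict_proba(X, batch_size=3)
        p3 = PatchCNN(ArchConfig(width_scale=1 / 16), seed=0).predict_proba(X)
        assert np.allclose(p1, p2, atol=1e-6)
        assert np.allclose(p1, p3)

    def test_wrong_patch_shape_rejected(self):
        net = PatchCNN(ArchConfig(width_scale=1 / 16), seed=0)
        with pytest.raises(ValueError):
            net.logits(np.zeros((2, 16, 16)))

    def test_backprop_matches_finite_differences(self):
        net = PatchCNN(ArchConfig(width_scale=0.03), seed=3, dtype=np.float64)
        rng = np.random.default_rng(0)
        # move biases off zero so no ReLU input sits exactly on the kink
        for _, layer, name in net.parameters():
            layer.params[name] = layer.params[name] + rng.normal(0.0, 0.05, layer.params[name].shape)
        X = rng.random((3, 32, 32))
        yb = np.array([1, 0, 1])

        def loss():
            z = net.logits(X)
            p = np.clip(softmax(z)[:, 1], 1e-7, 1 - 1e-7)
            return float(np.mean(focal_loss(p, yb, 0.9, 2.0)))

        z = net.logits(X, train=True)
        net.backward(_focal_grad_logits(z, yb, 0.9, 2.0))
        for key, layer, name in net.parameters():
            W, g = layer.params[name], layer.grads[name]
            for _ in range(3):
                ix = tuple(rng.integers(0, s) for s in W.shape)
                eps, old = 1e-6, W[ix]
                W[ix] = old + eps
                lp = loss()
                W[ix] = old - eps
                lm = loss()
                W[ix] = old
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - g[ix]) <= 1e-4 * (abs(fd) + abs(g[ix])) + 1e-8, key


class TestObjective:
    def test_perfect_batch_without_penalty_is_near_zero(self):
        net = PatchCNN(ArchConfig(width_scale=1 / 16), seed=0)
        X, y = toy_stripe_set(64, 0)
        trained = train(X, y, Hyper(width_scale=1 / 16, epochs=3, seed=0, mu=0.0))
        j = objective(trained, X, y, Hyper(width_scale=1 / 16, mu=0.0))
        assert j < 0.05

    def test_zero_weights_have_zero_penalty(self):
        net = PatchCNN(ArchConfig(width_scale=1 / 16), seed=0)
        for _, layer, name in net.parameters():
            layer.params[name] = np.zeros_like(layer.params[name])
        X = np.zeros((4, 32, 32), dtype=np.float32)
        y = np.array([0, 1, 0, 1])
        j = objective(net, X, y, Hyper(width_scale=1 / 16, mu=0.1))
        assert j == pytest.approx(float(np.mean(focal_loss(np.full(4, 0.5), y, 0.9, 2.0))))

    def test_hand_built_batch_decomposes(self):
        net = PatchCNN(ArchConfig(width_scale=1 / 16), seed=1)
        X = np.random.default_rng(3).random((2, 32, 32)).astype(np.float32)
        y = np.array([1, 0])
        h = Hyper(width_scale=1 / 16, mu=0.01)
        p = net.predict_proba(X)
        expected = np.mean([focal_loss(p[0], 1, h.alpha, h.gamma),
                            focal_loss(p[1], 0, h.alpha, h.gamma)])
        expected += 0.5 * h.mu * net.param_vector_sq_norm()
        assert objective(net, X, y, h) == pytest.approx(expected, rel=1e-6)


class TestTraining:
    def test_separable_toy_task_learned(self):
        X, y = toy_stripe_set(2000, 0)
        net = train(X, y, Hyper(width_scale=1 / 16, epochs=3, seed=0))
        pred = (net.predict_proba(X) >= 0.5).astype(int)
        assert np.mean(pred[y == 1] == 1) >= 0.95
        assert np.mean(pred[y == 0] == 0) >= 0.95

    def test_focal_weighting_helps_rare_class_recall(self):
        X, y = toy_stripe_set(1320, 1, pos_frac=1 / 12)  # about 1:11 imbalance
        focal = train(X, y, Hyper(width_scale=1 / 16, epochs=2, seed=0, alpha=0.9, gamma=2.0))
        plain = train(X, y, Hyper(width_scale=1 / 16, epochs=2, seed=0, alpha=0.5, gamma=0.0))
        rec_focal = np.mean(focal.predict_proba(X)[y == 1] >= 0.5)
        rec_plain = np.mean(plain.predict_proba(X)[y == 1] >= 0.5)
        assert rec_focal >= rec_plain

    def test_zero_epochs_returns_seeded_initialization(self):
        X, y = toy_stripe_set(64, 0)
        net = train(X, y, Hyper(width_scale=1 / 16, epochs=0, seed=5))
        ref = PatchCNN(ArchConfig(width_scale=1 / 16), seed=5)
        for (k1, l1, n1), (k2, l2, n2) in zip(net.parameters(), ref.parameters()):
            assert np.array_equal(l1.params[n1], l2.params[n2])

    def test_training_deterministic_given_seed(self):
        X, y = toy_stripe_set(256, 2)
        a = train(X, y, Hyper(width_scale=1 / 16, epochs=1, seed=9))
        b = train(X, y, Hyper(width_scale=1 / 16, epochs=1, seed=9))
        for (k1, l1, n1), (k2, l2, n2) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(l1.params[n1], l2.params[n2])

    def test_single_class_dataset_rejected(self):
        X = np.zeros((8, 32, 32), dtype=np.float32)
        with pytest.raises(ValueError, match="class-1"):
            train(X, np.zeros(8, dtype=int), Hyper(width_scale=1 / 16, epochs=1))

    def test_checkpoint_round_trip(self, tmp_path):
        X, y = toy_stripe_set(64, 0)
        h = Hyper(width_scale=1 / 16, epochs=1, seed=0)
        net = train(X, y, h)
        save_checkpoint(tmp_path / "ckpt.npz", net, h)
        net2, h2 = load_checkpoint(tmp_path / "ckpt.npz")
        assert h2 == h
        assert np.allclose(net.predict_proba(X), net2.predict_proba(X))


def test_hyper_validation():
    with pytest.raises(ValueError):
        Hyper(alpha=1.5)
    with pytest.raises(ValueError):
        Hyper(gamma=-1.0)
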