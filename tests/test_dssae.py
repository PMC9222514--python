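"""Sparse autoencoder stack: losses, analytic gradients, training, prediction."""

import math

import numpy as np
import pytest

from osteosae.dssae import (
    DSSAEModel,
    SparseAutoencoder,
    TrainConfig,
    _pack,
    _sae_loss_grad_arrays,
    _unpack,
    decode,
    encode,
    kl_sparsity,
    load_model,
    logsig,
    predict,
    sae_loss,
    save_model,
    train_dssae,
    train_sae,
    weight_reg,
)


class TestLogsig:
    def test_values(self):
        assert logsig(0.0) == 0.5
        assert logsig(2.0) == pytest.approx(0.880797, abs=1e-6)

    def test_symmetry(self, rng):
        x = rng.normal(scale=5, size=50)
        np.testing.assert_allclose(logsig(x) + logsig(-x), 1.0, atol=1e-12)

    def test_overflow_safe(self):
        assert logsig(1e3) == 1.0
        assert logsig(-1e3) == 0.0


class TestEncodeDecode:
    def test_zero_parameters_give_half(self):
        sae = SparseAutoencoder(np.zeros((3, 4)), np.zeros(3), np.zeros((4, 3)), np.zeros(4))
        np.testing.assert_allclose(encode(sae, np.ones((2, 4))), 0.5)
        np.testing.assert_allclose(decode(sae, np.ones((2, 3))), 0.5)

    def test_hand_computed_code(self):
        sae = SparseAutoencoder(np.array([[1.0, -1.0], [0.5, 0.5]]), np.array([0.0, 1.0]),
                                np.zeros((2, 2)), np.zeros(2))
        c = encode(sae, np.array([[0.2, 0.6]]))
        np.testing.assert_allclose(c, [[logsig(-0.4), logsig(1.4)]], atol=1e-12)

    def test_batch_equals_stacked_single(self, rng):
        sae = SparseAutoencoder.init(5, 3, rng)
        Y = np.random.default_rng(1).uniform(size=(4, 5))
        batched = encode(sae, Y)
        single = np.vstack([encode(sae, Y[i]) for i in range(4)])
        np.testing.assert_allclose(batched, single, atol=1e-14)

    def test_reconstruction_dim_matches_input(self, rng):
        sae = SparseAutoencoder.init(7, 3, rng)
        Z = decode(sae, encode(sae, np.random.default_rng(2).uniform(size=(6, 7))))
        assert Z.shape == (6, 7)

    def test_dimension_mismatch_rejected(self, rng):
        sae = SparseAutoencoder.init(5, 3, rng)
        with pytest.raises(ValueError):
            encode(sae, np.ones((2, 4)))


class TestSparsityAndRegularizers:
    def test_kl_zero_at_target(self):
        assert kl_sparsity(0.05, np.full(7, 0.05)) == pytest.approx(0.0, abs=1e-12)

    def test_kl_closed_form(self):
        expected = 0.05 * math.log(0.25) + 0.95 * math.log(0.95 / 0.8)
        assert kl_sparsity(0.05, np.array([0.2])) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.093943, abs=1e-6)

    def test_kl_additive_over_units(self, rng):
        rh = rng.uniform(0.01, 0.99, size=6)
        total = kl_sparsity(0.1, rh)
        assert total == pytest.approx(sum(kl_sparsity(0.1, np.array([v])) for v in rh), abs=1e-12)

    def test_kl_nonnegative_and_convex_on_grid(self):
        grid = np.linspace(0.01, 0.99, 99)
        vals = np.array([kl_sparsity(0.05, np.array([v])) for v in grid])
        assert (vals >= -1e-12).all()
        second = vals[:-2] - 2 * vals[1:-1] + vals[2:]
        assert (second >= -1e-9).all()

    def test_kl_invalid_rho(self):
        with pytest.raises(ValueError):
            kl_sparsity(1.5, np.array([0.5]))

    def test_weight_reg_hand_sum(self):
        sae = SparseAutoencoder(np.array([[1.0, 2.0]]), np.zeros(1),
                                np.array([[2.0], [1.0]]), np.zeros(2))
        assert weight_reg(sae) == 5.0

    def test_weight_reg_quadratic_scaling(self, rng):
        sae = SparseAutoencoder.init(4, 3, rng)
        scaled = SparseAutoencoder(3 * sae.W_Y, sae.B_Y, 3 * sae.W_Z, sae.B_Z)
        assert weight_reg(scaled) == pytest.approx(9 * weight_reg(sae), rel=1e-12)


class TestSAELoss:
    def test_zero_when_perfect_and_unregularized(self):
        # logsig(0)=0.5 everywhere: constant-0.5 data reconstructs exactly
        sae = SparseAutoencoder(np.zeros((3, 4)), np.zeros(3), np.zeros((4, 3)), np.zeros(4),
                                c_s=0.0, c_w=0.0)
        assert sae_loss(sae, np.full((5, 4), 0.5)) == pytest.approx(0.0, abs=1e-12)

    def test_zero_parameter_composition(self):
        # zero parameters, 0.5 input: reconstruction term 0, KL at rho_hat=0.5
        sae = SparseAutoencoder(np.zeros((3, 4)), np.zeros(3), np.zeros((4, 3)), np.zeros(4),
                                rho=0.05, c_s=1.0, c_w=0.0)
        expected = kl_sparsity(0.05, np.full(3, 0.5))
        assert sae_loss(sae, np.full((1, 4), 0.5)) == pytest.approx(expected, abs=1e-12)

    def test_empty_batch_rejected(self, tiny_sae_fixture):
        sae, _ = tiny_sae_fixture
        with pytest.raises(ValueError):
            sae_loss(sae, np.empty((0, 6)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_analytic_gradient_matches_finite_differences(self, seed):
        """Central correctness gate: full-loss gradient vs central differences."""
        rng = np.random.default_rng(seed)
        sae = SparseAutoencoder.init(6, 4, rng, rho=0.05, c_s=1.0, c_w=1e-4)
        Y = rng.uniform(0.1, 0.9, size=(5, 6))
        loss, gWY, gBY, gWZ, gBZ = _sae_loss_grad_arrays(sae, Y)
        g = np.concatenate([gWY.ravel(), gBY, gWZ.ravel(), gBZ])
        theta = _pack(sae)
        eps = 1e-6
        num = np.zeros_like(theta)
        for i in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num[i] = (_sae_loss_grad_arrays(_unpack(tp, sae), Y)[0]
                      - _sae_loss_grad_arrays(_unpack(tm, sae), Y)[0]) / (2 * eps)
        rel = np.abs(g - num) / np.maximum(1e-8, np.abs(g) + np.abs(num))
        assert rel.max() < 1e-5


class TestTrainSAE:
    def test_manifold_reconstruction_improves(self):
        rng = np.random.default_rng(7)
        t = rng.uniform(-1, 1, size=(100, 1))
        Y = np.clip(0.5 + 0.3 * t * np.array([0.8, 0.6]), 0, 1)
        _, trace = train_sae(Y, (2, 1), TrainConfig(epochs=300, c_s=0.0, c_w=0.0, seed=7))
        assert trace[-1] < 0.1 * trace[0]

    def test_same_seed_identical_weights(self, separable_blobs):
        X, _ = separable_blobs
        Y = (X - X.min(0)) / (X.max(0) - X.min(0))
        a, _ = train_sae(Y, (10, 4), TrainConfig(epochs=20, seed=9))
        b, _ = train_sae(Y, (10, 4), TrainConfig(epochs=20, seed=9))
        assert np.array_equal(a.W_Y, b.W_Y) and np.array_equal(a.W_Z, b.W_Z)

    def test_sparsity_penalty_pulls_activations_toward_rho(self):
        rng = np.random.default_rng(13)
        Y = rng.uniform(0, 1, size=(80, 8))
        means = []
        for c_s in (0.0, 0.3, 1.0):
            sae, _ = train_sae(Y, (8, 6), TrainConfig(epochs=150, c_s=c_s, rho=0.05, seed=13))
            means.append(encode(sae, Y).mean())
        assert means[0] > means[1] > means[2]
        assert abs(means[2] - 0.05) < abs(means[0] - 0.05)

    def test_encoder_aligns_with_first_principal_component(self):
        """Unregularized 1-unit SAE in the linear regime recovers PC1."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(5)
        v = rng.normal(size=6)
        v /= np.linalg.norm(v)
        Y = np.clip(0.5 + 0.08 * rng.normal(size=(200, 1)) * v
                    + 0.005 * rng.normal(size=(200, 6)), 0, 1)
        sae, _ = train_sae(Y, (6, 1), TrainConfig(epochs=400, c_s=0.0, c_w=0.0, seed=5))
        w = sae.W_Y.ravel()
        w = w / np.linalg.norm(w)
        pc1 = PCA(n_components=1).fit(Y).components_[0]
        assert abs(w @ pc1) > 0.9


class TestDSSAE:
    def test_separable_blobs_zero_training_error(self, separable_blobs):
        X, y = separable_blobs
        model = train_dssae(X, y, hidden_dims=(64, 32, 16, 8), config=TrainConfig(epochs=80, seed=1))
        preds, P = predict(model, X)
        assert preds == list(y)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_full_batch_invariant_to_sample_order(self, separable_blobs):
        """With batch_size >= N the objective is a symmetric function of the
        samples, so reordering them must not change what the model learns
        (up to floating-point summation noise, checked at prediction level)."""
        X, y = separable_blobs
        order = np.random.default_rng(3).permutation(len(y))
        cfg = TrainConfig(epochs=80, seed=0)  # batch_size default >= N: full batch
        a = train_dssae(X, y, (64, 32, 16, 8), cfg)
        b = train_dssae(X[order], [y[i] for i in order], (64, 32, 16, 8), cfg)
        # loss itself is permutation-invariant (exact for the analytic value)
        Y01 = (X - a.scaler_min) / a.scaler_range
        assert sae_loss(a.saes[0], Y01) == pytest.approx(sae_loss(a.saes[0], Y01[order]), rel=1e-9)
        pa, _ = predict(a, X)
        pb, _ = predict(b, X)
        assert pa == pb

    def test_probabilities_invariant_to_duplication(self, separable_blobs):
        X, y = separable_blobs
        model = train_dssae(X, y, (16, 8, 4, 2), TrainConfig(epochs=15, seed=4))
        _, P1 = predict(model, X[:3])
        _, P2 = predict(model, np.vstack([X[:3], X[:1]]))
        np.testing.assert_allclose(P1, P2[:3], atol=1e-12)

    def test_softmax_shift_invariance(self, separable_blobs):
        X, y = separable_blobs
        model = train_dssae(X, y, (16, 8, 4, 2), TrainConfig(epochs=15, seed=4))
        _, P1 = predict(model, X[:5])
        model.softmax_B = model.softmax_B + 3.7  # common shift to all logits
        _, P2 = predict(model, X[:5])
        np.testing.assert_allclose(P1, P2, atol=1e-9)

    def test_dimension_chaining_enforced(self, rng):
        saes = [SparseAutoencoder.init(10, 6, rng), SparseAutoencoder.init(5, 3, rng)]
        with pytest.raises(ValueError):
            DSSAEModel(saes, np.zeros((2, 3)), np.zeros(2), ("a", "b"),
                       np.zeros(10), np.ones(10))

    def test_label_feature_mismatch_rejected(self, separable_blobs):
        X, y = separable_blobs
        with pytest.raises(ValueError):
            train_dssae(X, y[:-1], (4, 3, 2, 2), TrainConfig(epochs=2))

    def test_serialization_roundtrip_bit_exact(self, separable_blobs, tmp_path):
        X, y = separable_blobs
        model = train_dssae(X, y, (16, 8, 4, 2), TrainConfig(epochs=10, seed=6))
        save_model(model, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        assert back.class_names == model.class_names
        for a, b in zip(model.saes, back.saes):
            assert np.array_equal(a.W_Y, b.W_Y) and np.array_equal(a.B_Z, b.B_Z)
        assert np.array_equal(model.softmax_W, back.softmax_W)
        pa, _ = predict(model, X[:10])
        pb, _ = predict(back, X[:10])
        assert pa == pb

    def test_minibatch_path_trains(self, separable_blobs):
        X, y = separable_blobs
        model = train_dssae(X, y, (64, 32, 16, 8),
                            TrainConfig(epochs=150, batch_size=32, seed=2))
        preds, _ = predict(model, X)
        errors = sum(p != t for p, t in zip(preds, y))
        assert errors / len(y) < 0.1
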