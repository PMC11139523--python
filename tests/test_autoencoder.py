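"""Autoencoder: loss terms, architecture constraints, training behaviour."""

import numpy as np
import pytest

from sigxae import (
    SBSCatalogue,
    XAEConfig,
    min_volume_penalty,
    poisson_nll,
)
from sigxae.autoencoder import (
    PoissonMinVolumeAutoencoder,
    build_model,
    encode,
    reconstruct,
    reconstruction_error,
    train_model,
)


class TestPoissonNLL:
    def test_direct_values(self):
        assert poisson_nll(np.array([2.0]), np.array([1.0])) == pytest.approx(1.0, abs=1e-5)
        assert poisson_nll(np.array([0.0]), np.array([0.5])) == pytest.approx(0.5, abs=1e-6)

    def test_stationary_at_xhat_equals_x(self):
        # The analytic minimum of -x log(xhat) + xhat is at xhat = x;
        # check by central finite differences at x = 7.
        x = np.array([7.0])
        h = 1e-4
        grad = (poisson_nll(x, x + h) - poisson_nll(x, x - h)) / (2 * h)
        assert abs(grad) < 1e-6

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            poisson_nll(np.zeros(3), np.ones(4))


class TestMinVolumePenalty:
    def test_zero_matrix(self):
        assert min_volume_penalty(np.zeros((96, 4)), beta=5.0) == 0.0

    def test_orthonormal_columns(self):
        W = np.zeros((96, 2))
        W[0, 0] = W[1, 1] = 1.0
        assert min_volume_penalty(W, 1.0) == pytest.approx(np.log(4.0), rel=1e-12)

    def test_sylvester_identity(self, rng):
        # log det(W W^T + I_96) computed directly agrees with the k x k form.
        W = rng.random((96, 4))
        big = np.linalg.slogdet(W @ W.T + np.eye(96))[1]
        assert min_volume_penalty(W, 1.0) == pytest.approx(big, rel=1e-8)

    def test_beta_scales_linearly(self, rng):
        W = rng.random((96, 3))
        assert min_volume_penalty(W, 2.0) == pytest.approx(
            2 * min_volume_penalty(W, 1.0), rel=1e-12)


class TestBuildModel:
    def test_decoder_shape_and_nonnegativity(self):
        model = build_model(XAEConfig(latent_dim=5))
        assert model.W.shape == (96, 5)
        assert (model.W >= 0).all()

    def test_deterministic_initialization(self):
        a = build_model(XAEConfig(latent_dim=3, seed=7)).W
        b = build_model(XAEConfig(latent_dim=3, seed=7)).W
        assert np.array_equal(a, b)

    def test_latent_nonnegative_on_untrained_model(self, rng):
        model = build_model(XAEConfig(latent_dim=4))
        z = model.transform(rng.poisson(5, (10, 96)))
        assert (z >= 0).all()

    def test_wide_latent_warns(self):
        with pytest.warns(UserWarning, match="narrowest"):
            XAEConfig(latent_dim=64, encoder_units=(32, 32, 32))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            XAEConfig(latent_dim=0)
        with pytest.raises(ValueError):
            XAEConfig(latent_dim=2, patience=100, max_epochs=50)


class TestTraining:
    def test_zero_epochs_leaves_weights_unchanged(self, rank1_catalogue,
                                                  tiny_xae_factory):
        cat, _ = rank1_catalogue
        cfg = tiny_xae_factory(1, max_epochs=0, patience=0)
        model = build_model(cfg)
        W0 = model.W
        train_model(model, cat)
        assert np.array_equal(model.W, W0)

    def test_rank1_reconstruction(self, rank1_catalogue, tiny_xae_factory):
        # Exactly rank-1 data with k=1 is representable: every row of the
        # reconstruction should align with its input almost perfectly.
        cat, profile = rank1_catalogue
        cfg = tiny_xae_factory(1, beta=0.0, seed=2)
        model = build_model(cfg).fit(cat)
        xhat = reconstruct(model, cat)
        X = cat.counts
        cosines = (xhat * X).sum(1) / (
            np.linalg.norm(xhat, axis=1) * np.linalg.norm(X, axis=1))
        assert cosines.min() >= 0.99

    def test_decoder_nonnegative_after_training(self, rank1_catalogue,
                                                tiny_xae_factory):
        cat, _ = rank1_catalogue
        model = build_model(tiny_xae_factory(2, max_epochs=5, patience=2))
        model.fit(cat)
        assert (model.W >= 0).all()

    def test_training_reduces_loss(self, planted_cohort_factory,
                                   tiny_xae_factory):
        cat, _, _ = planted_cohort_factory(2, 80, 800, seed=3)
        improved = 0
        for seed in range(5):
            model = build_model(tiny_xae_factory(2, seed=seed, max_epochs=25,
                                                 patience=24))
            model.fit(cat)
            hist = [h["train_nll"] for h in model.history]
            if hist[-1] < hist[0]:
                improved += 1
        assert improved >= 4

    def test_min_volume_regularizer_shrinks_logdet(self, planted_cohort_factory,
                                                   tiny_xae_factory):
        # Stronger beta must reduce log det(W^T W + I) on average.
        cat, _, _ = planted_cohort_factory(3, 60, 600, seed=4)
        logdets = {0.0: [], 25.0: []}
        for beta in logdets:
            for seed in range(3):
                cfg = tiny_xae_factory(3, beta=beta, seed=seed, max_epochs=40,
                                       patience=39)
                model = build_model(cfg).fit(cat)
                logdets[beta].append(min_volume_penalty(model.W, 1.0))
        assert np.mean(logdets[25.0]) < np.mean(logdets[0.0])

    def test_gradients_match_finite_differences(self, rng):
        # Backprop through dense layers, batch norm, softplus, the burden
        # scaling and both penalties agrees with numerical derivatives.
        X = rng.poisson(5, size=(9, 96)).astype(float)
        cfg = XAEConfig(latent_dim=3, encoder_units=(12, 10, 8), seed=1,
                        beta=0.5, latent_batchnorm=True)
        model = PoissonMinVolumeAutoencoder(cfg)
        import copy
        for key in model.params:
            model.params[key] = model.params[key].astype(np.float64)
        run0 = copy.deepcopy(model.running)

        def loss():
            model.running.update(copy.deepcopy(run0))
            cache = model._forward(X, training=True)
            return sum(model._loss_terms(X, cache))

        model.running.update(copy.deepcopy(run0))
        cache = model._forward(X, training=True)
        grads = model._backward(X, cache)
        for key in ("enc0_W", "bn1_gamma", "lat_W", "bn3_beta", "dec_W"):
            P = model.params[key]
            idx = tuple(rng.integers(0, s) for s in P.shape)
            h = 1e-6 * max(1.0, abs(P[idx]))
            old = P[idx]
            P[idx] = old + h
            lp = loss()
            P[idx] = old - h
            lm = loss()
            P[idx] = old
            num = (lp - lm) / (2 * h)
            assert grads[key][idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestPersistence:
    def test_checkpoint_roundtrip(self, tmp_path, rank1_catalogue,
                                  tiny_xae_factory):
        cat, _ = rank1_catalogue
        model = build_model(tiny_xae_factory(2, max_epochs=8, patience=2))
        model.fit(cat)
        path = tmp_path / "model.npz"
        model.save(path)
        back = PoissonMinVolumeAutoencoder.load(path)
        assert np.array_equal(back.W, model.W)
        assert np.allclose(back.predict(cat), model.predict(cat))
        assert back.config == model.config

    def test_history_frame(self, rank1_catalogue, tiny_xae_factory):
        cat, _ = rank1_catalogue
        model = build_model(tiny_xae_factory(1, max_epochs=5, patience=2))
        model.fit(cat)
        frame = model.history_frame()
        assert {"epoch", "train_nll", "monitored_loss"} <= set(frame.columns)
        assert len(frame) >= 1


class TestInference:
    def test_perfect_reconstruction_zero_error(self, rank1_catalogue):
        cat, _ = rank1_catalogue
        X = cat.counts.astype(float)

        class Identity:
            def predict(self, C):
                return X

        assert reconstruction_error(Identity(), cat) == 0.0

    def test_3_4_5_frobenius(self):
        # ||[[3,4],[0,0]] - 0||_F = 5 on a 2-entry toy; embed in 96 channels.
        X = np.zeros((2, 96))
        X[0, 0], X[0, 1] = 3, 4

        class Zero:
            def predict(self, C):
                return np.zeros_like(X)

        assert reconstruction_error(Zero(), X) == pytest.approx(5.0)

    def test_frobenius_matches_elementwise_oracle(self, rng):
        X = rng.poisson(6, (7, 96)).astype(float)
        pred = rng.random((7, 96)) * 6

        class Fixed:
            def predict(self, C):
                return pred

        oracle = np.sqrt(((X - pred) ** 2).sum())
        assert reconstruction_error(Fixed(), X) == pytest.approx(oracle, rel=1e-9)

    def test_encode_returns_nonnegative_exposures(self, rank1_catalogue,
                                                  tiny_xae_factory):
        cat, _ = rank1_catalogue
        model = build_model(tiny_xae_factory(2, max_epochs=5, patience=2)).fit(cat)
        Z = encode(model, cat)
        assert (Z.values >= 0).all()
        assert Z.values.shape == (50, 2)
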