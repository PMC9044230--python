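"""Standardization, PCA, the autoencoder variants, and item assignment."""

import numpy as np
import pytest

from psychae import (
    ReducerConfig,
    SCENARIOS,
    TrainingError,
    assign_from_weights,
    assign_items,
    fit_autoencoder,
    fit_pca,
    fit_reducer,
    generate,
    mse,
    standardize_apply,
    standardize_fit,
)
from psychae.reducers import FittedReducer


class TestStandardizer:
    def test_training_data_becomes_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        data = rng.normal(5, 3, size=(100, 4))
        z = standardize_apply(standardize_fit(data), data)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-12)

    def test_constant_column_rejected(self):
        data = np.ones((10, 3))
        data[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match=r"\[1, 2\]"):
            standardize_fit(data)

    def test_row_at_training_mean_maps_to_zero(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(50, 3))
        scaler = standardize_fit(data)
        np.testing.assert_allclose(
            scaler.transform(data.mean(axis=0, keepdims=True)), 0, atol=1e-12
        )


class TestPCA:
    def test_components_are_orthonormal(self, high_split_2000):
        train, _ = high_split_2000
        model = fit_pca(train, 3)
        np.testing.assert_allclose(
            model.components @ model.components.T, np.eye(3), atol=1e-10
        )

    def test_full_basis_reconstructs_exactly(self, high_split_2000):
        train, test = high_split_2000
        model = fit_pca(train, 15)
        assert mse(test, model.reconstruct(test)) < 1e-10

    def test_too_many_components_rejected(self, high_split_2000):
        with pytest.raises(ValueError):
            fit_pca(high_split_2000[0], 16)

    def test_population_mse_matches_residual_eigenvalue_sum(self, structures):
        # high matrix spectrum leaves 12 * 0.3 / 15 = 0.24 unexplained by k=3
        dataset = generate(structures["high"], SCENARIOS["s1"], 100_000, seed=3)
        z = standardize_apply(standardize_fit(dataset.data), dataset.data)
        model = fit_pca(z, 3)
        assert mse(z, model.reconstruct(z)) == pytest.approx(0.240, abs=0.01)


class TestAutoencoders:
    def test_same_seed_gives_identical_weights(self, high_split_2000):
        train, _ = high_split_2000
        config = ReducerConfig("tied_ae", seed=8, epochs=30)
        a = fit_autoencoder(train, config)
        b = fit_autoencoder(train, config)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_tied_decoder_is_encoder_transpose(self, high_split_2000):
        model = fit_autoencoder(
            high_split_2000[0], ReducerConfig("tied_ae", seed=1, epochs=20)
        )
        eff = model._effective_weights()
        assert np.shares_memory(eff[0], eff[1].base) or np.array_equal(
            eff[0].T, eff[1]
        )

    def test_tied_matches_pca_floor_on_test_data(self, high_split_2000):
        # Eckart-Young: no linear bottleneck-3 reconstruction beats PCA(3)
        train, test = high_split_2000
        mse_pca = mse(test, fit_pca(train, 3).reconstruct(test))
        tied = fit_autoencoder(train, ReducerConfig("tied_ae", seed=5))
        mse_tied = mse(test, tied.reconstruct(test))
        assert abs(mse_tied - mse_pca) <= 0.02
        assert mse_tied >= mse_pca - 0.02

    def test_tied_encoder_recovers_principal_subspace(self, structures):
        # principal angles between the learned row space and the top-3
        # eigenvector span of the population matrix
        dataset = generate(structures["high"], SCENARIOS["s1"], 10_000, seed=19)
        z = standardize_apply(standardize_fit(dataset.data), dataset.data)
        model = fit_autoencoder(z, ReducerConfig("tied_ae", seed=2))
        w, v = np.linalg.eigh(structures["high"].matrix)
        top3 = v[:, np.argsort(w)[::-1][:3]]
        q, _ = np.linalg.qr(model.weights[0])
        angles = np.degrees(np.arccos(np.clip(
            np.linalg.svd(top3.T @ q, compute_uv=False), -1, 1)))
        assert np.all(angles < 5.0)

    def test_deep_network_fits_noiseless_rank3_data(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((1000, 3)) @ rng.standard_normal((3, 15))
        z = standardize_apply(standardize_fit(data), data)
        model = fit_autoencoder(z, ReducerConfig("deep_ae", seed=4, epochs=1000))
        assert model.loss_history[-1] < 1e-3

    def test_covariance_penalty_decorrelates_latents(self, high_split_2000):
        train, _ = high_split_2000
        offdiags = []
        for lam in (0.0, 0.1, 1.0):
            model = fit_autoencoder(
                train,
                ReducerConfig("independent_ae", seed=5, penalty_covariance=lam),
            )
            cov = np.cov(model.encode(train).T)
            offdiags.append(np.abs(cov - np.diag(np.diag(cov))).mean())
        assert offdiags[0] >= offdiags[1] >= offdiags[2]

    @pytest.mark.parametrize(
        "variant", ["simple_ae", "tied_ae", "deep_ae", "independent_ae"]
    )
    def test_full_batch_loss_is_monotone(self, variant, structures):
        dataset = generate(structures["high"], SCENARIOS["s2"], 400, seed=21)
        z = standardize_apply(standardize_fit(dataset.data), dataset.data)
        model = fit_autoencoder(
            z, ReducerConfig(variant, seed=77, epochs=200, batch_size=400)
        )
        losses = np.array(model.loss_history)
        start = max(1, len(losses) // 10)
        assert np.all(np.diff(losses[start:]) <= 1e-6)

    def test_exploding_learning_rate_raises(self, high_split_2000):
        with pytest.raises(TrainingError, match="epoch"):
            fit_autoencoder(
                high_split_2000[0],
                ReducerConfig("simple_ae", seed=1, learning_rate=50.0, epochs=50),
            )

    def test_encode_reconstruct_shapes_and_mismatch(self, high_split_2000):
        train, test = high_split_2000
        model = fit_autoencoder(train, ReducerConfig("simple_ae", seed=1, epochs=10))
        assert model.encode(test).shape == (400, 3)
        assert model.reconstruct(test).shape == test.shape
        with pytest.raises(ValueError, match="expected"):
            model.encode(test[:, :10])

    def test_serialization_round_trip(self, high_split_2000):
        train, test = high_split_2000
        for config in (ReducerConfig("deep_ae", seed=2, epochs=15), None):
            model = (
                fit_autoencoder(train, config) if config else fit_pca(train, 3)
            )
            clone = FittedReducer.from_dict(model.to_dict())
            np.testing.assert_allclose(
                clone.reconstruct(test), model.reconstruct(test), atol=1e-12
            )


class TestAssignment:
    def test_largest_weight_wins(self):
        # single-row weight patterns and their expected construct
        weights = np.array([[0.329, 0.029, 0.237], [0.104, 0.19, 0.581]])
        assignment = assign_from_weights(weights)
        assert assignment.construct.tolist() == [1, 3]

    def test_identity_weights_assign_diagonally(self):
        assignment = assign_from_weights(np.eye(3))
        assert assignment.construct.tolist() == [1, 2, 3]

    def test_ties_break_low_with_warning(self):
        with pytest.warns(UserWarning, match="tied"):
            assignment = assign_from_weights(np.array([[0.5, 0.5, 0.1]]))
        assert assignment.construct.tolist() == [1]

    def test_model_assignment_uses_linearized_deep_weights(self, high_split_2000):
        train, _ = high_split_2000
        model = fit_autoencoder(train, ReducerConfig("deep_ae", seed=3, epochs=10))
        assignment = assign_items(model)
        assert assignment.weights.shape == (15, 3)
        assert set(assignment.construct) <= {1, 2, 3}

    def test_fit_reducer_dispatch(self, high_split_2000):
        train, _ = high_split_2000
        assert fit_reducer(train, ReducerConfig("pca")).variant == "pca"
        with pytest.raises(ValueError, match="variant"):
            ReducerConfig("kernel_pca")
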