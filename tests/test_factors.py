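"""Latent factor estimation, projection, and response regression."""

import numpy as np
import pandas as pd
import pytest

from lsfactor import (
    CohortConfig,
    LatentModel,
    compute_loadings,
    estimate_latent_factors,
    factor_similarity,
    fit_response,
    plant_pseudobulk,
    predict_response,
    standardize,
)
from lsfactor.preprocess import PseudobulkMatrix


def _std_frame(arr, cols=None):
    df = pd.DataFrame(np.asarray(arr, dtype=float), columns=cols)
    return (df - df.mean()) / df.std(ddof=1)


def _truth_model(truth):
    return LatentModel(
        K=truth.weight_matrix_true.shape[1],
        weight_matrix=truth.weight_matrix_true,
        factor_names=truth.factor_names,
        hyperparams={},
        pure_features={},
    )


def _planted(seed, K=10, snr=5.0, n=300, **kw):
    per = n // 4
    cfg = CohortConfig(n_adult_case=per, n_ped_case=per, n_adult_control=per,
                       n_ped_control=per, n_clusters=5, genes_per_cluster_pool=20,
                       seed=seed)
    return plant_pseudobulk(cfg, K=K, snr=snr, **kw)


class TestEstimateLatentFactors:
    def test_two_disjoint_blocks_recovered_exactly(self):
        """Block-diagonal correlation: K=2, modules = blocks, no overlap."""
        rng = np.random.default_rng(0)
        z = rng.standard_normal((200, 2))
        X = np.column_stack([z[:, 0]] * 4 + [z[:, 1]] * 4) + rng.normal(0, 0.3, (200, 8))
        model = estimate_latent_factors(_std_frame(X), delta=0.1)
        assert model.K == 2
        W = model.weight_matrix.to_numpy()
        block1, block2 = (W[:4] != 0), (W[4:] != 0)
        k1 = int(np.flatnonzero(block1.any(axis=0))[0])
        assert block1[:, k1].all() and not block1[:, 1 - k1].any()
        assert block2[:, 1 - k1].all() and not block2[:, k1].any()

    def test_planted_modules_recovered_with_high_cosine(self):
        """Every planted module is matched with |cosine| >= 0.9 at snr=5."""
        pb, _, truth = _planted(seed=0, K=10, snr=5.0)
        model = estimate_latent_factors(standardize(pb))
        sims = factor_similarity(_truth_model(truth), model)
        assert len(sims) == 10
        assert min(c for _, _, c in sims) >= 0.9

    def test_pure_noise_raises_no_factors(self):
        rng = np.random.default_rng(3)
        X = _std_frame(rng.standard_normal((100, 30)))
        with pytest.raises(ValueError, match="no factors"):
            estimate_latent_factors(X, delta=0.6)

    def test_deterministic(self):
        pb, _, _ = _planted(seed=1)
        a = estimate_latent_factors(standardize(pb))
        b = estimate_latent_factors(standardize(pb))
        pd.testing.assert_frame_equal(a.weight_matrix, b.weight_matrix)

    def test_each_factor_has_pure_features(self):
        pb, _, _ = _planted(seed=1)
        model = estimate_latent_factors(standardize(pb))
        W = model.weight_matrix
        for name in model.factor_names:
            pure = model.pure_features[name]
            assert len(pure) >= 1
            sub = W.loc[pure]
            assert (sub[name] != 0).all()
            assert (sub.drop(columns=[name]) == 0).all().all()

    def test_recovery_improves_with_snr(self):
        """Mean best-match cosine is non-decreasing over snr in {2, 5, 10}."""
        means = []
        for snr in (2.0, 5.0, 10.0):
            cosines = []
            for seed in range(20):
                pb, _, truth = _planted(seed=seed, K=5, snr=snr, n=200)
                model = estimate_latent_factors(standardize(pb))
                sims = factor_similarity(_truth_model(truth), model)
                cosines.append(np.mean([c for _, _, c in sims]))
            means.append(np.mean(cosines))
        assert means[0] <= means[1] + 1e-6 <= means[2] + 2e-6

    def test_unstandardized_input_rejected(self):
        pb, _, _ = _planted(seed=1)
        with pytest.raises(ValueError, match="standardized"):
            estimate_latent_factors(pb)


class TestComputeLoadings:
    def test_orthonormal_weights_give_identity_scores(self):
        W = pd.DataFrame(np.eye(4, 2), index=[f"f{j}" for j in range(4)],
                         columns=["LF1", "LF2"])
        model = LatentModel(K=2, weight_matrix=W, factor_names=["LF1", "LF2"],
                            hyperparams={}, pure_features={})
        X = pd.DataFrame(W.to_numpy().T, columns=W.index)
        scores = compute_loadings(model, X).scores.to_numpy()
        np.testing.assert_allclose(scores, np.eye(2), atol=1e-12)

    def test_zero_matrix_gives_zero_scores(self):
        W = pd.DataFrame(np.eye(3, 2), index=list("abc"), columns=["LF1", "LF2"])
        model = LatentModel(K=2, weight_matrix=W, factor_names=["LF1", "LF2"],
                            hyperparams={}, pure_features={})
        X = pd.DataFrame(np.zeros((5, 3)), columns=list("abc"))
        assert (compute_loadings(model, X).scores.to_numpy() == 0).all()

    def test_matches_per_sample_least_squares_oracle(self):
        """scores agree with an independent per-sample normal-equations solve."""
        rng = np.random.default_rng(5)
        W = rng.standard_normal((8, 3))
        X = rng.standard_normal((5, 8))
        feats = [f"f{j}" for j in range(8)]
        model = LatentModel(
            K=3,
            weight_matrix=pd.DataFrame(W, index=feats, columns=["LF1", "LF2", "LF3"]),
            factor_names=["LF1", "LF2", "LF3"],
            hyperparams={},
            pure_features={},
        )
        scores = compute_loadings(model, pd.DataFrame(X, columns=feats)).scores.to_numpy()
        oracle = np.vstack([np.linalg.solve(W.T @ W, W.T @ x) for x in X])
        np.testing.assert_allclose(scores, oracle, atol=1e-10)

    def test_feature_mismatch_errors(self):
        W = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["LF1", "LF2"])
        model = LatentModel(K=2, weight_matrix=W, factor_names=["LF1", "LF2"],
                            hyperparams={}, pure_features={})
        with pytest.raises(ValueError, match="[Ff]eature mismatch"):
            compute_loadings(model, pd.DataFrame(np.ones((2, 2)), columns=["a", "c"]))

    def test_projection_reproduces_training_scores(self):
        """Projecting the training matrix is a fixed point of the fit."""
        pb, _, _ = _planted(seed=2)
        Xs = standardize(pb)
        model = estimate_latent_factors(Xs)
        s1 = compute_loadings(model, Xs).scores
        s2 = compute_loadings(model, Xs).scores
        pd.testing.assert_frame_equal(s1, s2)


class TestFitResponse:
    def test_exact_linear_response_recovered(self):
        rng = np.random.default_rng(0)
        Z = pd.DataFrame(rng.standard_normal((30, 2)), columns=["LF1", "LF2"])
        y = 2.5 * Z["LF1"].to_numpy() + 1.0
        fit = fit_response(Z, y, task="continuous")
        assert fit.coef["LF1"] == pytest.approx(2.5, abs=1e-8)
        assert fit.coef["LF2"] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fit.fitted.to_numpy(), y, atol=1e-8)

    def test_constant_response_gives_zero_slopes(self):
        rng = np.random.default_rng(1)
        Z = pd.DataFrame(rng.standard_normal((20, 3)), columns=["LF1", "LF2", "LF3"])
        fit = fit_response(Z, np.full(20, 4.0), task="continuous")
        np.testing.assert_allclose(fit.coef.to_numpy(), 0.0, atol=1e-8)
        assert fit.intercept == pytest.approx(4.0)

    def test_six_sample_toy_matches_normal_equations(self):
        Z = pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [-1.0, 0.5], [0.5, -1.0], [0.0, 0.0]],
            columns=["LF1", "LF2"],
        )
        y = np.array([1.0, 2.0, 2.5, 0.0, -0.5, 1.0])
        D = np.column_stack([np.ones(6), Z.to_numpy()])
        beta_oracle = np.linalg.solve(D.T @ D, D.T @ y)
        fit = fit_response(Z, y, task="continuous")
        np.testing.assert_allclose(
            [fit.intercept, *fit.coef.to_numpy()], beta_oracle, atol=1e-10
        )

    def test_binary_fit_separable_data_is_finite(self):
        """Perfect separation falls back to the ridge solution gracefully."""
        Z = pd.DataFrame({"LF1": [-2.0, -1.5, -1.0, 1.0, 1.5, 2.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        fit = fit_response(Z, y, task="binary")
        assert np.isfinite(fit.coef["LF1"])
        assert ((fit.fitted > 0.5).astype(int).to_numpy() == y).all()

    def test_interaction_terms_round_trip_through_prediction(self):
        rng = np.random.default_rng(4)
        Z = pd.DataFrame(rng.standard_normal((50, 2)), columns=["LF1", "LF2"])
        y = Z["LF1"] * Z["LF2"] + 0.1 * rng.standard_normal(50)
        fit = fit_response(Z, y.to_numpy(), task="continuous",
                           terms=["LF1", "LF2", ("LF1", "LF2")])
        preds = predict_response(fit, Z)
        np.testing.assert_allclose(preds.to_numpy(), fit.fitted.to_numpy(), atol=1e-10)
        assert fit.coef["LF1*LF2"] != 0.0


class TestSerialization:
    def test_model_round_trip(self, tmp_path):
        pb, _, _ = _planted(seed=6)
        model = estimate_latent_factors(standardize(pb))
        model.save(tmp_path / "model")
        back = LatentModel.load(tmp_path / "model")
        pd.testing.assert_frame_equal(model.weight_matrix, back.weight_matrix)
        assert back.K == model.K
        assert back.hyperparams == model.hyperparams
        assert back.pure_features == model.pure_features
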