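"""Cross-validation, permutation nulls, grouped holdout, cohort transfer."""

import numpy as np
import pandas as pd
import pytest

from lsfactor import (
    CohortConfig,
    PipelineSpec,
    compute_auc,
    cross_predict,
    factor_similarity,
    fit_pipeline,
    grouped_cv,
    kfold_cv,
    permutation_null,
    plant_pseudobulk,
    simulate_transfer_cohort,
    transfer_clusters,
)
from lsfactor.factors import LatentModel

from conftest import cells_from_counts, small_cohort


def _single_factor_model(vec, feats, name="LF1"):
    W = pd.DataFrame({name: vec}, index=feats)
    return LatentModel(K=1, weight_matrix=W, factor_names=[name],
                       hyperparams={}, pure_features={})


class TestComputeAuc:
    def test_perfect_ranking(self):
        assert compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_reversed_ranking(self):
        assert compute_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_ties_counted_half_by_pair_enumeration(self):
        """scores (0.9, 0.4, 0.4) with labels (1, 1, 0): 1 win + 1 tie of 2 pairs."""
        assert compute_auc([0.9, 0.4, 0.4], [1, 1, 0]) == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            compute_auc([0.1, 0.2], [1, 1])


class TestKfoldCV:
    def test_perfectly_separating_module_gives_auc_one(self):
        """A module that exactly encodes the labels yields AUC 1 in every repeat."""
        rng = np.random.default_rng(0)
        n = 44
        y = np.array([1] * 27 + [0] * 17)
        z_noise = rng.standard_normal(n)
        X = pd.DataFrame(
            np.column_stack(
                [y * 2.0 + rng.normal(0, 0.05, n) for _ in range(4)]
                + [z_noise + rng.normal(0, 0.05, n) for _ in range(4)]
            ),
            columns=[f"c0:g{j}" for j in range(8)],
        )
        rep = kfold_cv(X, y, k=5, n_repeats=3, spec=PipelineSpec(task="binary"), seed=0)
        assert all(m == 1.0 for m in rep.metrics)

    def test_strong_planted_signal_has_high_heldout_auc(self, planted_default):
        """Held-out AUC on the strong-signal 44-sample cohort (snr=5)."""
        pb, y, _ = planted_default
        rep = kfold_cv(pb, y.to_numpy(), k=5, n_repeats=5,
                       spec=PipelineSpec(task="binary"), seed=3)
        assert np.mean(rep.metrics) >= 0.9

    def test_shuffled_labels_center_at_chance(self, planted_default):
        pb, y, _ = planted_default
        rng = np.random.default_rng(1)
        y_shuf = rng.permutation(y.to_numpy())
        rep = kfold_cv(pb, y_shuf, k=5, n_repeats=5,
                       spec=PipelineSpec(task="binary"), seed=1)
        assert abs(np.mean(rep.metrics) - 0.5) < 0.15

    def test_fold_assignments_partition_samples(self, planted_default):
        pb, y, _ = planted_default
        rep = kfold_cv(pb, y.to_numpy(), k=5, n_repeats=2,
                       spec=PipelineSpec(task="binary"), seed=2)
        for test_sets in rep.fold_assignments:
            flat = np.concatenate(test_sets)
            assert sorted(flat) == list(range(pb.n_samples))

    def test_k_below_two_rejected(self, planted_default):
        pb, y, _ = planted_default
        with pytest.raises(ValueError):
            kfold_cv(pb, y.to_numpy(), k=1)


class TestPermutationNull:
    def test_real_signal_dominates_null(self, planted_default):
        pb, y, _ = planted_default
        rep = permutation_null(pb, y.to_numpy(), k=5, n_repeats=10, n_perms=10,
                               spec=PipelineSpec(task="binary"), seed=4)
        assert rep.p_value < 0.01
        assert np.mean(rep.metrics) > np.mean(rep.null_metrics)

    def test_null_distribution_reproducible(self, planted_default):
        pb, y, _ = planted_default
        a = permutation_null(pb, y.to_numpy(), k=5, n_repeats=2, n_perms=3,
                             spec=PipelineSpec(task="binary"), seed=5)
        b = permutation_null(pb, y.to_numpy(), k=5, n_repeats=2, n_perms=3,
                             spec=PipelineSpec(task="binary"), seed=5)
        assert a.null_metrics == b.null_metrics
        assert a.metrics == b.metrics


class TestGroupedCV:
    def test_site_holdout_partition_is_disjoint(self, planted_default):
        """No sample appears in both training and test for any held-out site."""
        pb, y, _ = planted_default
        groups = pb.sample_meta["site_group"].to_numpy()
        res = grouped_cv(pb, y.to_numpy(), groups, PipelineSpec(task="binary"), seed=0)
        assert set(res) == {"trunk", "extremity"}
        for g, entry in res.items():
            assert len(set(entry["train_index"]) & set(entry["test_index"])) == 0
            assert (groups[entry["test_index"]] == g).all()
            assert (groups[entry["train_index"]] != g).all()

    def test_group_invariant_signal_transfers_across_sites(self):
        """Signal planted independently of site: both held-out sites score high."""
        cfg = small_cohort(seed=0)
        pb, y, _ = plant_pseudobulk(cfg, K=10, snr=5.0)
        groups = pb.sample_meta["site_group"].to_numpy()
        res = grouped_cv(pb, y.to_numpy(), groups, PipelineSpec(task="binary"), seed=0)
        for g, entry in res.items():
            assert entry["metric"] >= 0.8

    def test_single_group_rejected(self, planted_default):
        pb, y, _ = planted_default
        with pytest.raises(ValueError):
            grouped_cv(pb, y.to_numpy(), np.repeat("trunk", pb.n_samples))


class TestTransferClusters:
    def test_identical_cell_gets_its_own_cluster(self):
        ref = cells_from_counts(
            [[5.0, 0.0, 1.0], [4.0, 1.0, 1.0], [0.0, 5.0, 2.0], [1.0, 4.0, 2.0]],
            ["S1"] * 4, ["cA", "cA", "cB", "cB"],
        )
        query = cells_from_counts([[5.0, 0.0, 1.0]], ["Q1"], ["?"])
        labels = transfer_clusters(ref, query)
        assert labels.iloc[0] == "cA"

    def test_two_cluster_toy_matches_hand_centroids(self):
        """Assignment agrees with the exhaustive correlation-to-centroid solve."""
        ref = cells_from_counts(
            [[10.0, 0.0, 5.0], [8.0, 2.0, 5.0], [0.0, 10.0, 5.0], [2.0, 8.0, 5.0]],
            ["S1"] * 4, ["cA", "cA", "cB", "cB"],
        )
        q = np.array([[7.0, 3.0, 5.0], [3.0, 7.0, 5.0]])
        query = cells_from_counts(q, ["Q1", "Q1"], ["?", "?"])
        labels = transfer_clusters(ref, query)

        centroids = {"cA": np.array([9.0, 1.0, 5.0]), "cB": np.array([1.0, 9.0, 5.0])}
        for i in range(2):
            corr = {c: np.corrcoef(q[i], v)[0, 1] for c, v in centroids.items()}
            assert labels.iloc[i] == max(corr, key=corr.get)

    def test_no_shared_genes_errors(self):
        ref = cells_from_counts([[1.0, 2.0]], ["S1"], ["cA"], gene_names=["g1", "g2"])
        query = cells_from_counts([[1.0, 2.0]], ["Q1"], ["?"], gene_names=["h1", "h2"])
        with pytest.raises(ValueError, match="shared"):
            transfer_clusters(ref, query)


class TestCrossPredict:
    def test_identity_transfer_is_exact(self, planted_default):
        """Predicting the training cohort reproduces in-sample predictions."""
        pb, y, _ = planted_default
        bundle = fit_pipeline(pb, y.to_numpy(), PipelineSpec(task="binary"), seed=0)
        res = cross_predict(bundle.model, bundle.response_fit, pb, y.to_numpy())
        np.testing.assert_allclose(
            res.predictions.to_numpy(),
            bundle.response_fit.fitted.to_numpy(),
            atol=1e-10,
        )
        assert res.dropped_from_model == []

    def test_synthetic_transfer_cohort_auc(self):
        """Mean transfer AUC across seeds under 10% feature dropout."""
        aucs = []
        for seed in range(10):
            cfg = small_cohort(seed=seed)
            pb, y, truth = plant_pseudobulk(cfg, K=10, snr=5.0)
            bundle = fit_pipeline(pb, y.to_numpy(), PipelineSpec(task="binary"), seed=seed)
            qcfg = small_cohort(seed=100 + seed, n_adult_case=10, n_ped_case=10,
                                n_adult_control=10, n_ped_control=10)
            qpb, qy = simulate_transfer_cohort(truth, qcfg, feature_dropout=0.1)
            res = cross_predict(bundle.model, bundle.response_fit, qpb, qy.to_numpy())
            aucs.append(res.metric)
        assert np.mean(aucs) >= 0.8

    def test_missing_features_removed_from_both_sides(self, planted_default):
        pb, y, _ = planted_default
        bundle = fit_pipeline(pb, y.to_numpy(), PipelineSpec(task="binary"), seed=0)
        drop = pb.feature_names[:7]
        query = pb.copy()
        query.values = query.values.drop(columns=drop)
        res = cross_predict(bundle.model, bundle.response_fit, query, y.to_numpy())
        assert set(res.dropped_from_model) == set(drop) & set(bundle.model.feature_names)
        assert set(res.matched_features).isdisjoint(drop)
        assert set(res.matched_features) <= set(query.feature_names)

    def test_continuous_transfer_refits_and_preserves_factors(self):
        cfg = small_cohort(seed=2)
        pb, y, truth = plant_pseudobulk(cfg, K=10, snr=5.0, response_kind="continuous")
        bundle = fit_pipeline(pb, y.to_numpy(), PipelineSpec(task="continuous"), seed=2)
        qpb, qy = simulate_transfer_cohort(truth, small_cohort(seed=55), feature_dropout=0.05)
        res = cross_predict(
            bundle.model, bundle.response_fit, qpb, qy.to_numpy(),
            X_train=pb, y_train=y.to_numpy(),
        )
        assert res.metric_name == "spearman_rho"
        assert res.metric > 0.7
        matched_cos = [c for _, _, c in res.factor_cosines]
        assert np.median(matched_cos) > 0.9

    def test_empty_intersection_errors(self, planted_default):
        pb, y, _ = planted_default
        bundle = fit_pipeline(pb, y.to_numpy(), PipelineSpec(task="binary"), seed=0)
        query = pb.copy()
        query.values.columns = [f"other:{c}" for c in query.values.columns]
        with pytest.raises(ValueError, match="overlap"):
            cross_predict(bundle.model, bundle.response_fit, query, y.to_numpy())


class TestFactorSimilarity:
    def test_identical_models_all_cosines_one(self, planted_default):
        pb, y, _ = planted_default
        bundle = fit_pipeline(pb, y.to_numpy(), PipelineSpec(task="binary"), seed=0)
        sims = factor_similarity(bundle.model, bundle.model)
        assert all(c == pytest.approx(1.0) for _, _, c in sims)

    def test_orthogonal_single_factor_models(self):
        a = _single_factor_model([1.0, 0.0], ["f1", "f2"])
        b = _single_factor_model([0.0, 1.0], ["f1", "f2"])
        sims = factor_similarity(a, b)
        assert sims[0][2] == pytest.approx(0.0)

    def test_two_dimensional_closed_form(self):
        a = _single_factor_model([1.0, 0.0], ["f1", "f2"])
        b = _single_factor_model([1.0 / np.sqrt(2), 1.0 / np.sqrt(2)], ["f1", "f2"])
        sims = factor_similarity(a, b)
        assert sims[0][2] == pytest.approx(1.0 / np.sqrt(2))

    def test_disjoint_features_error(self):
        a = _single_factor_model([1.0], ["f1"])
        b = _single_factor_model([1.0], ["f2"])
        with pytest.raises(ValueError):
            factor_similarity(a, b)
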