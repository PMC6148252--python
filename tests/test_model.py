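"""Co-clustering model: conjugate updates, ELBO contracts, recovery, pruning."""

import math

import numpy as np
import pytest

from mvcoclust.analysis import adjusted_rand_index
from mvcoclust.data import DataMatrix, FeatureSpec
from mvcoclust.model import (Hyperparameters, block_posterior_update, fit,
                             fit_single, plugin_loglik, prune)


class TestConjugateUpdates:
    def test_zero_observations_return_the_prior(self):
        hp = Hyperparameters()
        post = block_posterior_update([], "numerical", hp)
        assert post["mean"] == hp.mu0
        assert post["lam"] == hp.lambda0
        assert post["shape"] == hp.gamma0 / 2
        assert post["rate"] == hp.gamma0 * hp.sigma0_sq / 2
        post = block_posterior_update([], "categorical", hp, n_levels=3)
        np.testing.assert_allclose(post["concentration"], [1.0, 1.0, 1.0])
        post = block_posterior_update([], "integer", hp)
        assert (post["shape"], post["rate"]) == (hp.a0, hp.b0)

    def test_dirichlet_counts_3_1_give_expectation_4_6_2_6(self):
        post = block_posterior_update([0, 0, 0, 1], "categorical",
                                      Hyperparameters(), n_levels=2)
        np.testing.assert_allclose(post["mean_probs"], [4 / 6, 2 / 6])

    def test_poisson_sum_7_over_3_gives_gamma_8_4(self):
        post = block_posterior_update([2, 2, 3], "integer", Hyperparameters())
        assert post["shape"] == 8.0
        assert post["rate"] == 4.0
        assert post["mean_rate"] == pytest.approx(2.0)

    def test_normal_gamma_three_point_hand_computation(self):
        # x = {1, 2, 3}; hp defaults: lambda0 = 0.01, mu0 = 0,
        # gamma0 = sigma0^2 = 0.01.
        hp = Hyperparameters()
        post = block_posterior_update([1.0, 2.0, 3.0], "numerical", hp)
        lam = 0.01 + 3
        m = (0.01 * 0.0 + 6.0) / lam
        shape = 0.01 / 2 + 3 / 2
        # sum of squared deviations from the sample mean 2 is 2
        rate = 0.01 * 0.01 / 2 + 0.5 * 2.0 + 0.5 * 0.01 * 3 / lam * (2.0 - 0.0) ** 2
        assert post["lam"] == pytest.approx(lam)
        assert post["mean"] == pytest.approx(m)
        assert post["shape"] == pytest.approx(shape)
        assert post["rate"] == pytest.approx(rate)

    def test_fractional_weights_interpolate_counts(self):
        hp = Hyperparameters()
        post = block_posterior_update([1.0, 1.0], "integer", hp, weights=[0.5, 0.5])
        assert post["shape"] == pytest.approx(hp.a0 + 1.0)
        assert post["rate"] == pytest.approx(hp.b0 + 1.0)

    def test_hyperparameters_must_be_positive(self):
        with pytest.raises(ValueError):
            Hyperparameters(alpha1=0.0)


class TestFitSingle:
    def test_recovers_two_clusters_at_ten_sd_separation(self, two_cluster_matrix):
        dm, truth = two_cluster_matrix
        sol = fit(dm, truncation=(2, 2, 4), n_restarts=10, base_seed=0)
        assert sol.n_views == 1
        assert sol.n_subject_clusters(0) == 2
        assert adjusted_rand_index(sol.subject_clusters[0], truth) == 1.0

    def test_elbo_trace_is_non_decreasing(self, two_cluster_matrix):
        dm, _ = two_cluster_matrix
        for seed in range(5):
            sol = fit_single(dm, truncation=(2, 2, 4), seed=seed)
            diffs = np.diff(sol.elbo_trace)
            assert diffs.min() >= -1e-8 * max(1.0, abs(sol.elbo))

    def test_constant_data_collapses_to_single_block(self):
        dm = DataMatrix(np.full((12, 6), 3.0), [f"s{i}" for i in range(12)],
                        [FeatureSpec(f"f{j}", "numerical") for j in range(6)])
        sol = fit(dm, truncation=(3, 3, 3), n_restarts=5, base_seed=0)
        assert sol.n_views == 1
        assert sol.n_subject_clusters(0) == 1
        assert int(sol.feature_cluster.max()) == 0

    def test_infinite_values_rejected(self):
        dm = DataMatrix(np.array([[1.0], [np.inf]]), ["a", "b"],
                        [FeatureSpec("x", "numerical")])
        with pytest.raises(ValueError, match="finite"):
            fit_single(dm, truncation=(1, 1, 1))

    def test_fully_missing_feature_does_not_perturb_recovery(self, two_cluster_matrix):
        dm, truth = two_cluster_matrix
        vals = np.hstack([dm.values, np.full((dm.n_subjects, 1), np.nan)])
        dm2 = DataMatrix(vals, dm.subject_ids,
                         dm.specs + [FeatureSpec("allmiss", "numerical")])
        sol = fit(dm2, truncation=(2, 2, 4), n_restarts=10, base_seed=0)
        v = sol.feature_view[0]
        assert adjusted_rand_index(sol.subject_clusters[v], truth) == 1.0

    def test_single_view_truncation_matches_full_model_on_one_view_data(
            self, two_cluster_matrix):
        dm, truth = two_cluster_matrix
        lbm = fit(dm, truncation=(1, 2, 4), n_restarts=10, base_seed=0)
        full = fit(dm, truncation=(3, 2, 4), n_restarts=10, base_seed=0)
        assert lbm.n_views == 1
        assert adjusted_rand_index(lbm.subject_clusters[0], truth) == 1.0
        assert adjusted_rand_index(full.subject_clusters[full.feature_view[0]],
                                   truth) == 1.0


class TestFitRestarts:
    def test_one_restart_equals_fit_single(self, two_cluster_matrix):
        dm, _ = two_cluster_matrix
        a = fit(dm, truncation=(2, 2, 4), n_restarts=1, base_seed=3)
        b = fit_single(dm, truncation=(2, 2, 4), seed=3)
        assert a.elbo == b.elbo
        np.testing.assert_array_equal(a.subject_clusters, b.subject_clusters)
        np.testing.assert_array_equal(a.feature_view, b.feature_view)

    def test_selected_solution_maximizes_selection_score(self, two_cluster_matrix):
        dm, _ = two_cluster_matrix
        sol = fit(dm, truncation=(2, 2, 4), n_restarts=8, base_seed=0)
        assert sol.elbo == max(sol.restart_elbos)
        assert len(sol.restart_scores) == 8
        sol2 = fit(dm, truncation=(2, 2, 4), n_restarts=8, base_seed=0,
                   select="loglik")
        assert sol2.plugin_loglik == max(sol2.restart_scores)


class TestPluginLoglik:
    def _small(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, (6, 4))
        specs = [FeatureSpec(f"f{j}", "numerical") for j in range(4)]
        return DataMatrix(vals, [f"s{i}" for i in range(6)], specs)

    def test_label_permutation_invariance(self):
        dm = self._small()
        hp = Hyperparameters()
        fv = np.array([0, 0, 1, 1])
        fc = np.array([0, 1, 0, 0])
        sc = np.array([[0, 0, 1, 1, 0, 1], [0, 1, 0, 1, 0, 1]])
        base = plugin_loglik(dm, fv, fc, sc, hp)
        # permute subject-cluster labels within view 0 and view order
        sc_perm = np.array([1 - sc[1], 1 - sc[0]])
        fv_perm = 1 - fv
        assert plugin_loglik(dm, fv_perm, fc, sc_perm, hp) == pytest.approx(base)

    def test_hard_block_parameters_match_single_block_update(self):
        dm = self._small()
        hp = Hyperparameters()
        sol = fit_single(dm, hp, truncation=(1, 1, 1), seed=0)
        post = block_posterior_update(dm.values.ravel(), "numerical", hp)
        blk = sol.blocks[0]["numerical"]
        assert blk["mean"][0, 0] == pytest.approx(post["mean"])
        assert blk["precision"][0, 0] == pytest.approx(post["mean_precision"])


class TestPrune:
    def test_prune_without_empty_components_preserves_comembership(self, two_cluster_matrix):
        dm, _ = two_cluster_matrix
        sol = fit(dm, truncation=(2, 2, 4), n_restarts=5, base_seed=0)
        pruned = prune(sol, dm)
        assert pruned.n_views == sol.n_views
        for v in range(sol.n_views):
            assert adjusted_rand_index(pruned.subject_clusters[v],
                                       sol.subject_clusters[v]) == 1.0
        assert adjusted_rand_index(pruned.feature_view, sol.feature_view) == 1.0
        assert pruned.elbo == sol.elbo

    def test_fitted_solutions_have_no_empty_components(self, two_cluster_matrix):
        dm, _ = two_cluster_matrix
        sol = fit(dm, truncation=(3, 3, 5), n_restarts=5, base_seed=1)
        for v in range(sol.n_views):
            assert np.flatnonzero(sol.feature_view == v).size > 0
            used = np.unique(sol.subject_clusters[v])
            np.testing.assert_array_equal(used, np.arange(used.size))


class TestSolutionIo:
    def test_write_then_read_reproduces_assignments_exactly(self, two_cluster_matrix,
                                                            tmp_path):
        from mvcoclust.data import read_solution_assignments, write_solution

        dm, _ = two_cluster_matrix
        sol = fit(dm, truncation=(2, 2, 4), n_restarts=3, base_seed=0)
        write_solution(sol, tmp_path)
        fv, fc, subjects, sc = read_solution_assignments(tmp_path)
        assert subjects == sol.subject_ids
        np.testing.assert_array_equal(sc, sol.subject_clusters)
        for j, name in enumerate(sol.feature_names):
            assert fv[name] == sol.feature_view[j]
            assert fc[name] == sol.feature_cluster_label(j)

    def test_prune_drops_an_artificially_emptied_view(self, two_cluster_matrix):
        dm, _ = two_cluster_matrix
        sol = fit(dm, truncation=(2, 2, 4), n_restarts=3, base_seed=0)
        # pretend the solution was fitted with a spare view holding nothing
        sol.subject_clusters = np.vstack([sol.subject_clusters,
                                          np.zeros(dm.n_subjects, dtype=int)])
        pruned = prune(sol, dm)
        assert pruned.n_views == 1


class TestDeterminism:
    def test_same_seed_same_solution(self, two_cluster_matrix):
        dm, _ = two_cluster_matrix
        a = fit(dm, truncation=(2, 2, 4), n_restarts=3, base_seed=5)
        b = fit(dm, truncation=(2, 2, 4), n_restarts=3, base_seed=5)
        assert a.elbo == b.elbo
        np.testing.assert_array_equal(a.subject_clusters, b.subject_clusters)
        assert a.restart_scores == b.restart_scores
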