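"""View characterization: PC scores, ARI, Cohen's d, screens, consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mvcoclust.analysis import (adjusted_rand_index, average_cohens_d, cohens_d,
                                depression_feature_proportion, feature_significance,
                                first_pc_scores, hamming_consensus,
                                pc_correlation_matrix, sensitivity_sweep,
                                solution_agreement, view_fc_pc_scores,
                                view_report_table)
from mvcoclust.data import DataMatrix, FeatureSpec
from mvcoclust.model import CoClusterSolution, Hyperparameters, fit, fit_single


# ---------------------------------------------------------------------------
# adjusted Rand index vs an independent pair-counting oracle
# ---------------------------------------------------------------------------

def _ari_pair_counting(a, b):
    """Hubert-Arabie ARI from explicit enumeration of subject pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    n00 = n01 = n10 = n11 = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        if sa and sb:
            n11 += 1
        elif sa and not sb:
            n10 += 1
        elif sb and not sa:
            n01 += 1
        else:
            n00 += 1
    total = n11 + n10 + n01 + n00
    expected = (n11 + n10) * (n11 + n01) / total
    maximum = 0.5 * ((n11 + n10) + (n11 + n01))
    if maximum == expected:
        return 1.0
    return (n11 - expected) / (maximum - expected)


def _partitions(n):
    """All set partitions of range(n), as label vectors."""
    if n == 1:
        yield [0]
        return
    for part in _partitions(n - 1):
        k = max(part) + 1
        for c in range(k + 1):
            yield part + [c]


class TestAdjustedRandIndex:
    def test_identical_partitions_score_exactly_one(self):
        part = [0, 0, 1, 2, 1]
        assert adjusted_rand_index(part, part) == 1.0

    def test_singletons_vs_one_cluster_score_zero(self):
        assert adjusted_rand_index(range(6), np.zeros(6)) == 0.0

    def test_example_matches_pair_counting(self):
        a, b = [1, 1, 2, 2], [1, 2, 1, 2]
        assert adjusted_rand_index(a, b) == pytest.approx(_ari_pair_counting(a, b))

    def test_exhaustive_agreement_on_all_partitions_of_five(self):
        parts = list(_partitions(5))          # all 52 set partitions
        for a in parts:
            for b in parts:
                assert adjusted_rand_index(a, b) == pytest.approx(
                    _ari_pair_counting(a, b), abs=1e-12)

    def test_random_partitions_of_six_match_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.integers(0, 4, 6)
            b = rng.integers(0, 3, 6)
            assert adjusted_rand_index(a, b) == pytest.approx(
                _ari_pair_counting(a, b), abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([0, 1], [0, 1, 2])


# ---------------------------------------------------------------------------
# first principal component
# ---------------------------------------------------------------------------

class TestFirstPc:
    def test_rank_one_case_scores_proportional_to_feature(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal(50)
        X = np.c_[f, f]
        scores, load = first_pc_scores(X)
        r = np.corrcoef(scores, f)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert (load >= 0).all()

    def test_planted_factor_recovered_at_n_500(self):
        rng = np.random.default_rng(2)
        factor = rng.standard_normal(500)
        X = np.outer(factor, rng.uniform(0.5, 1.5, 20)) \
            + 0.3 * rng.standard_normal((500, 20))
        scores, _ = first_pc_scores(X)
        assert abs(np.corrcoef(scores, factor)[0, 1]) >= 0.99

    def test_global_sign_flip_leaves_scores_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 5)) + rng.standard_normal(40)[:, None]
        s1, _ = first_pc_scores(X)
        s2, _ = first_pc_scores(-X)
        np.testing.assert_allclose(s1, -s2, atol=1e-10)
        # orientation rule: majority of loadings non-negative in both cases
        _, l1 = first_pc_scores(X)
        _, l2 = first_pc_scores(-X)
        assert (l1 > 0).sum() >= (l1 < 0).sum()
        assert (l2 > 0).sum() >= (l2 < 0).sum()

    def test_fewer_than_two_features_rejected(self):
        with pytest.raises(ValueError):
            first_pc_scores(np.ones((10, 1)))


# ---------------------------------------------------------------------------
# fitted-solution statistics on a planted two-view matrix
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_two_view():
    rng = np.random.default_rng(4)
    n = 80
    partA = np.repeat([0, 1], 40)
    partB = np.tile([0, 1], 40)
    factorA = np.where(partA == 0, -2.0, 2.0) + 0.5 * rng.standard_normal(n)
    factorB = np.where(partB == 0, -2.0, 2.0) + 0.5 * rng.standard_normal(n)
    XA = factorA[:, None] + 0.5 * rng.standard_normal((n, 8))
    XB = factorB[:, None] + 0.5 * rng.standard_normal((n, 8))
    specs = ([FeatureSpec(f"fcA{j}", "numerical", group="FC") for j in range(8)]
             + [FeatureSpec(f"fcB{j}", "numerical", group="FC") for j in range(8)])
    labels = {f"s{i}": ("depressed" if partA[i] else "control") for i in range(n)}
    dm = DataMatrix(np.hstack([XA, XB]), [f"s{i}" for i in range(n)], specs, labels)
    sol = fit(dm, truncation=(4, 2, 4), n_restarts=10, base_seed=0)
    return dm, sol, partA, partB


class TestPcCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, fitted_two_view):
        dm, sol, *_ = fitted_two_view
        C = pc_correlation_matrix(sol, dm)
        np.testing.assert_array_equal(C, C.T)
        assert np.allclose(np.diag(C)[~np.isnan(np.diag(C))], 1.0)

    def test_independent_planted_factors_give_low_cross_correlation(self, fitted_two_view):
        dm, sol, partA, partB = fitted_two_view
        assert sol.n_views >= 2
        C = pc_correlation_matrix(sol, dm)
        off = C[0, 1]
        assert abs(off) < 0.3        # independent factors, n = 80

    def test_ineligible_view_marked_nan(self):
        # single numerical non-FC feature -> no FC-eligible view
        dm = DataMatrix(np.random.default_rng(0).standard_normal((10, 1)),
                        [f"s{i}" for i in range(10)],
                        [FeatureSpec("q", "numerical")])
        sol = fit_single(dm, truncation=(1, 1, 2), seed=0)
        C = pc_correlation_matrix(sol, dm)
        assert np.isnan(C).all()
        assert view_fc_pc_scores(sol, dm, 0) is None


class TestDepressionProportion:
    def _solution_with_specs(self, specs):
        d = len(specs)
        dm = DataMatrix(np.zeros((4, d)) + np.arange(d), [f"s{i}" for i in range(4)],
                        specs)
        sol = fit_single(dm, truncation=(1, 1, 1), seed=0)
        return dm, sol

    def test_view_of_only_fc_features_scores_zero(self):
        specs = [FeatureSpec(f"fc{j}", "numerical", group="FC") for j in range(3)]
        dm, sol = self._solution_with_specs(specs)
        prop = depression_feature_proportion(sol, dm, 0)
        assert prop["proportion_all"] == 0.0
        assert prop["proportion_non_fc"] is None

    def test_three_flagged_of_five_counted_gives_point_six(self):
        specs = ([FeatureSpec(f"q{j}", "numerical", depression_related=j < 3)
                  for j in range(5)])
        dm, sol = self._solution_with_specs(specs)
        assert depression_feature_proportion(sol, dm, 0)["proportion_non_fc"] == 0.6

    def test_all_flagged_gives_one(self):
        specs = [FeatureSpec(f"q{j}", "numerical", depression_related=True)
                 for j in range(4)]
        dm, sol = self._solution_with_specs(specs)
        assert depression_feature_proportion(sol, dm, 0)["proportion_non_fc"] == 1.0


def _toy_solution(means, precisions, n_fc=5, n_dep_per_cluster=5):
    """Hand-built single-view solution with given Gaussian block params."""
    G, K = np.asarray(means).shape
    n = K * n_dep_per_cluster
    d = G * n_fc
    specs = [FeatureSpec(f"fc{j}", "numerical", group="FC") for j in range(d)]
    labels = {f"s{i}": "depressed" for i in range(n)}
    dm = DataMatrix(np.zeros((n, d)), [f"s{i}" for i in range(n)], specs, labels)
    blocks = [{"numerical": {"mean": np.asarray(means, float),
                             "precision": np.asarray(precisions, float),
                             "lam": np.ones((G, K)), "shape": np.ones((G, K)),
                             "rate": np.ones((G, K)),
                             "features_per_cluster": np.full(G, n_fc)}}]
    return dm, CoClusterSolution(
        feature_names=[s.name for s in specs], feature_dtypes=["numerical"] * d,
        subject_ids=list(dm.subject_ids),
        feature_view=np.zeros(d, int),
        feature_cluster=np.repeat(np.arange(G), n_fc),
        subject_clusters=np.repeat(np.arange(K), n_dep_per_cluster)[None, :],
        blocks=blocks, elbo=0.0, elbo_trace=[0.0], plugin_loglik=0.0,
        hyperparameters=Hyperparameters(), truncation=(1, G, K), seed=0)


class TestAverageCohensD:
    def test_two_blocks_unit_variance_gap_08(self):
        dm, sol = _toy_solution([[0.0, 0.8]], [[1.0, 1.0]])
        assert average_cohens_d(sol, dm, 0) == pytest.approx(0.8)

    def test_three_means_0_1_3_average_1_5(self):
        dm, sol = _toy_solution([[0.0, 1.0, 3.0]], [[1.0, 1.0, 1.0]])
        assert average_cohens_d(sol, dm, 0) == pytest.approx(1.5)

    def test_equal_means_give_zero(self):
        dm, sol = _toy_solution([[2.0, 2.0]], [[1.0, 1.0]])
        assert average_cohens_d(sol, dm, 0) == pytest.approx(0.0)

    def test_invariant_under_cluster_relabeling(self):
        dm, sol = _toy_solution([[0.0, 1.0, 3.0]], [[1.0, 1.0, 1.0]])
        base = average_cohens_d(sol, dm, 0)
        dm2, sol2 = _toy_solution([[3.0, 0.0, 1.0]], [[1.0, 1.0, 1.0]])
        perm = np.array([2, 0, 1])[sol.subject_clusters[0]]
        sol2.subject_clusters = perm[None, :]
        assert average_cohens_d(sol2, dm2, 0) == pytest.approx(base)

    def test_ineligible_small_clusters_excluded(self):
        # third subject cluster has fewer than four depressed members
        dm, sol = _toy_solution([[0.0, 1.0, 9.0]], [[1.0, 1.0, 1.0]],
                                n_dep_per_cluster=5)
        small = sol.subject_clusters[0] == 2
        labels = dict(dm.labels)
        for i in np.flatnonzero(small)[2:]:
            labels[dm.subject_ids[i]] = "control"
        dm.labels = labels
        assert average_cohens_d(sol, dm, 0) == pytest.approx(1.0)

    def test_feature_cluster_with_too_few_fc_features_excluded(self):
        dm, sol = _toy_solution([[0.0, 5.0], [0.0, 1.0]], [[1.0] * 2] * 2, n_fc=5)
        # shrink cluster 0 below four FC features by retyping them
        sol.feature_cluster = np.array([0, 0, 0, 1, 1] + [1] * 5)
        assert average_cohens_d(sol, dm, 0) == pytest.approx(1.0)

    def test_formula(self):
        assert cohens_d(0.0, 1.0, 1.0, 2.0) == pytest.approx(1.0 / np.sqrt(2.5))


class TestFeatureSignificance:
    def _fit_planted(self):
        rng = np.random.default_rng(5)
        n = 40
        part = np.repeat([0, 1], 20)
        strong = np.where(part == 0, -5.0, 5.0) + rng.standard_normal(n)
        flat = rng.standard_normal(n)
        cat = np.where(rng.random(n) < np.where(part == 0, 0.9, 0.1), 0.0, 1.0)
        specs = [FeatureSpec("strong", "numerical"),
                 FeatureSpec("flat", "numerical"),
                 FeatureSpec("item", "categorical", levels=("a", "b"))]
        dm = DataMatrix(np.c_[strong, flat, cat], [f"s{i}" for i in range(n)], specs)
        sol = fit(dm, truncation=(2, 2, 3), n_restarts=8, base_seed=0)
        return dm, sol

    def test_separated_numerical_feature_is_significant(self):
        dm, sol = self._fit_planted()
        v = int(sol.feature_view[0])
        table = feature_significance(sol, dm, v)
        row = table.set_index("feature").loc["strong"]
        assert row["significant"]
        assert row["p"] < row["threshold"]

    def test_constant_feature_not_significant(self):
        dm, sol = _toy_solution([[0.0, 1.0]], [[1.0, 1.0]])
        table = feature_significance(sol, dm, 0)
        assert not table["significant"].any()
        assert (table["p"] == 1.0).all()

    def test_bonferroni_threshold_with_single_feature_is_005(self):
        rng = np.random.default_rng(6)
        n = 30
        cat = (rng.random(n) < 0.5).astype(float)
        dm = DataMatrix(cat[:, None], [f"s{i}" for i in range(n)],
                        [FeatureSpec("item", "categorical", levels=("a", "b"))])
        sol = fit_single(dm, truncation=(1, 1, 2), seed=0)
        if sol.n_subject_clusters(0) >= 2:
            table = feature_significance(sol, dm, 0)
            assert table["threshold"].iloc[0] == pytest.approx(0.05)


class TestHammingConsensus:
    def _solution_with_partitions(self, parts):
        parts = np.asarray(parts)
        V, n = parts.shape
        d = V
        specs = [FeatureSpec(f"f{j}", "numerical") for j in range(d)]
        dm = DataMatrix(np.zeros((n, d)), [f"s{i}" for i in range(n)], specs)
        return CoClusterSolution(
            feature_names=[s.name for s in specs], feature_dtypes=["numerical"] * d,
            subject_ids=list(dm.subject_ids), feature_view=np.arange(d),
            feature_cluster=np.zeros(d, int), subject_clusters=parts,
            blocks=[{} for _ in range(V)], elbo=0.0, elbo_trace=[0.0],
            plugin_loglik=0.0, hyperparameters=Hyperparameters(),
            truncation=(V, 1, 2), seed=0)

    def test_always_coclustered_gives_zero(self):
        sol = self._solution_with_partitions(np.zeros((4, 3), int))
        D, _, _ = hamming_consensus(sol)
        np.testing.assert_array_equal(D, np.zeros((3, 3)))

    def test_always_differing_gives_one(self):
        sol = self._solution_with_partitions([[0, 1], [0, 1], [0, 1]])
        D, _, _ = hamming_consensus(sol)
        assert D[0, 1] == 1.0

    def test_differing_in_3_of_15_views_gives_02(self):
        parts = np.zeros((15, 2), int)
        parts[:3, 1] = 1
        sol = self._solution_with_partitions(parts)
        D, _, nwk = hamming_consensus(sol)
        assert D[0, 1] == pytest.approx(0.2)
        assert D[1, 0] == pytest.approx(0.2)
        assert np.all(np.diag(D) == 0)
        assert nwk.endswith(";") and "s0000" not in nwk

    def test_range_and_symmetry_on_fitted_solution(self, fitted_two_view):
        _, sol, *_ = fitted_two_view
        D, Z, nwk = hamming_consensus(sol)
        assert (D >= 0).all() and (D <= 1).all()
        np.testing.assert_array_equal(D, D.T)
        assert Z is not None


class TestSensitivity:
    def test_zero_perturbation_identical_seed_gives_ari_one(self, fitted_two_view):
        dm, *_ = fitted_two_view
        table = sensitivity_sweep(dm, Hyperparameters(), [{}],
                                  base_seed=0, n_restarts=3, truncation=(4, 2, 4))
        assert len(table) == 1
        assert table["view_ari"].iloc[0] == 1.0
        assert table["subject_ari"].iloc[0] == 1.0

    def test_one_row_per_grid_point_and_robustness(self, fitted_two_view):
        dm, *_ = fitted_two_view
        hp = Hyperparameters()
        grid = [{"alpha1": hp.alpha1 * f, "alpha2": hp.alpha2 * f,
                 "beta": hp.beta * f, "lambda0": hp.lambda0 * f,
                 "gamma0": hp.gamma0 * f, "sigma0_sq": hp.sigma0_sq * f,
                 "rho0": hp.rho0 * f, "a0": hp.a0 * f, "b0": hp.b0 * f}
                for f in (0.5, 1.5)]
        table = sensitivity_sweep(dm, hp, grid, base_seed=0, n_restarts=5,
                                  truncation=(4, 2, 4))
        assert len(table) == 2
        assert (table["subject_ari"] >= 0.9).all()


class TestReports:
    def test_view_report_table_shape_and_ranges(self, fitted_two_view):
        dm, sol, *_ = fitted_two_view
        table = view_report_table(sol, dm)
        assert len(table) == sol.n_views
        ari = table["ari_vs_labels"].dropna()
        assert ((ari >= -1) & (ari <= 1)).all()
        d = table["average_cohens_d"].dropna()
        assert (d >= 0).all()
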