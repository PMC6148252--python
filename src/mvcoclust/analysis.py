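"""Characterization of fitted co-clustering solutions.

Per-view statistics: first-principal-component subject scores of FC
features, between-view PC correlations, agreement with diagnosis labels
(adjusted Rand index), depression-related feature proportions, block
separability as average Cohen's d, per-feature ANOVA / chi-square screens
with Bonferroni correction within feature type, a Hamming-distance subject
consensus, and a hyperparameter sensitivity sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .data import CATEGORICAL, GROUP_FC, INTEGER, NUMERICAL, DataMatrix
from .model import CoClusterSolution, Hyperparameters, fit

__all__ = [
    "ViewReport",
    "first_pc_scores",
    "view_fc_pc_scores",
    "pc_correlation_matrix",
    "adjusted_rand_index",
    "depression_feature_proportion",
    "average_cohens_d",
    "cohens_d",
    "feature_significance",
    "hamming_consensus",
    "planted_recovery_scores",
    "sensitivity_sweep",
    "build_view_report",
    "view_report_table",
]


def cohens_d(mu1: float, mu2: float, sd1: float, sd2: float) -> float:
    """Standardized mean difference (mu2 - mu1) / sqrt((sd1^2 + sd2^2) / 2)."""
    return (mu2 - mu1) / np.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)


def adjusted_rand_index(a: Sequence, b: Sequence) -> float:
    """Hubert-Arabie adjusted Rand index: 0 at chance, 1 for identical partitions."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same subject set")
    return float(adjusted_rand_score(a, b))


# ---------------------------------------------------------------------------
# principal-component scores
# ---------------------------------------------------------------------------

def first_pc_scores(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leading principal-component scores of a complete (subjects x features) matrix.

    Columns are centred; the loading vector has unit norm and is oriented so
    that the majority of loadings are non-negative (ties broken toward a
    non-negative loading sum). Returns ``(scores, loadings)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 features")
    if np.isnan(X).any():
        raise ValueError("first_pc_scores requires a complete matrix; impute first")
    Xc = X - X.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    load = vt[0]
    n_neg = int((load < 0).sum())
    n_pos = int((load > 0).sum())
    if n_neg > n_pos or (n_neg == n_pos and load.sum() < 0):
        load = -load
    return Xc @ load, load


def _imputed_view_matrix(solution: CoClusterSolution, data: DataMatrix,
                         v: int, cols: np.ndarray) -> np.ndarray:
    """View submatrix with missing numerical entries replaced by block posterior means."""
    X = data.values[:, cols].copy()
    blk = solution.blocks[v].get(NUMERICAL)
    if blk is None:
        return X
    sc = solution.subject_clusters[v]
    for jj, j in enumerate(cols):
        g = int(solution.feature_cluster[j])
        miss = np.isnan(X[:, jj])
        if miss.any():
            X[miss, jj] = blk["mean"][g, sc[miss]]
    return X


def view_fc_pc_scores(solution: CoClusterSolution, data: DataMatrix,
                      v: int) -> np.ndarray | None:
    """First-PC subject scores over a view's FC features; None if < 2 FC features.

    Missing entries are imputed by the fitted block posterior mean so every
    subject receives a score.
    """
    fc_cols = data.group_indices(GROUP_FC)
    cols = np.intersect1d(solution.view_features(v), fc_cols)
    if cols.size < 2:
        return None
    X = _imputed_view_matrix(solution, data, v, cols)
    scores, _ = first_pc_scores(X)
    return scores


def pc_correlation_matrix(solution: CoClusterSolution, data: DataMatrix) -> np.ndarray:
    """View x view Pearson correlations of first-PC FC scores (NaN when ineligible)."""
    V = solution.n_views
    scores = [view_fc_pc_scores(solution, data, v) for v in range(V)]
    out = np.full((V, V), np.nan)
    for a in range(V):
        if scores[a] is None:
            continue
        out[a, a] = 1.0
        for b in range(a + 1, V):
            if scores[b] is None:
                continue
            r = float(np.corrcoef(scores[a], scores[b])[0, 1])
            out[a, b] = out[b, a] = r
    return out


# ---------------------------------------------------------------------------
# view-level statistics
# ---------------------------------------------------------------------------

def depression_feature_proportion(solution: CoClusterSolution, data: DataMatrix,
                                  v: int) -> dict:
    """Proportion of depression-related features in a view.

    FC features are never counted as depression-related. The primary
    proportion uses the view's non-FC features as denominator; the
    proportion over all view features is reported alongside, since either
    convention is defensible.
    """
    cols = solution.view_features(v)
    if cols.size == 0:
        return {"n_features": 0, "n_non_fc": 0, "n_flagged": 0,
                "proportion_non_fc": None, "proportion_all": None}
    specs = [data.specs[j] for j in cols]
    non_fc = [s for s in specs if s.group != GROUP_FC]
    flagged = [s for s in non_fc if s.depression_related]
    return {
        "n_features": len(specs),
        "n_non_fc": len(non_fc),
        "n_flagged": len(flagged),
        "proportion_non_fc": len(flagged) / len(non_fc) if non_fc else None,
        "proportion_all": len(flagged) / len(specs),
    }


#: eligibility thresholds: strictly more than three
MIN_FC_FEATURES_PER_CLUSTER = 4
MIN_DEPRESSED_PER_CLUSTER = 4


def average_cohens_d(solution: CoClusterSolution, data: DataMatrix, v: int,
                     depressed_mask: np.ndarray | None = None) -> float | None:
    """Average Cohen's d between neighboring fitted block means in a view.

    For each eligible FC feature cluster (> 3 FC features), the fitted
    Gaussian block means over eligible subject clusters (> 3 depressed
    subjects) are sorted and d = (mu2 - mu1)/sqrt((sigma2^2 + sigma1^2)/2)
    is evaluated between neighboring means (mu1 < mu2, so d >= 0); all d
    values in the view are averaged. Block sd is the inverse square root of
    the posterior-mean precision. Returns None when no cluster is eligible.
    """
    blk = solution.blocks[v].get(NUMERICAL)
    if blk is None:
        return None
    if depressed_mask is None:
        if data.labels is not None:
            depressed_mask = data.label_array() == "depressed"
        else:
            depressed_mask = np.ones(data.n_subjects, dtype=bool)
    sc = solution.subject_clusters[v]
    K = solution.n_subject_clusters(v)
    eligible_k = [k for k in range(K)
                  if int(((sc == k) & depressed_mask).sum()) >= MIN_DEPRESSED_PER_CLUSTER]
    if len(eligible_k) < 2:
        return None
    fc_cols = set(data.group_indices(GROUP_FC).tolist())
    cols = solution.view_features(v)
    num_cols = [j for j in cols if data.specs[j].dtype == NUMERICAL]
    ds: list[float] = []
    G = blk["mean"].shape[0]
    for g in range(G):
        n_fc = sum(1 for j in num_cols
                   if int(solution.feature_cluster[j]) == g and j in fc_cols)
        if n_fc < MIN_FC_FEATURES_PER_CLUSTER:
            continue
        means = blk["mean"][g, eligible_k]
        sds = 1.0 / np.sqrt(blk["precision"][g, eligible_k])
        order = np.argsort(means)
        mu, sd = means[order], sds[order]
        for a in range(len(mu) - 1):
            ds.append(cohens_d(mu[a], mu[a + 1], sd[a], sd[a + 1]))
    if not ds:
        return None
    return float(np.mean(ds))


def feature_significance(solution: CoClusterSolution, data: DataMatrix, v: int,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature screens for discrimination among a view's subject clusters.

    One-way ANOVA across subject clusters for numerical features; chi-square
    independence on the cluster x value crosstable for categorical and
    integer features. The significance threshold is Bonferroni-corrected
    within each feature type: ``alpha / m`` with ``m`` the number of tested
    features of that type in the view. Constant features get p = 1.
    """
    sc = solution.subject_clusters[v]
    cols = solution.view_features(v)
    rows = []
    for j in cols:
        spec = data.specs[j]
        col = data.values[:, j]
        obs = ~np.isnan(col)
        p = 1.0
        stat = np.nan
        groups = [col[(sc == k) & obs] for k in range(solution.n_subject_clusters(v))]
        groups = [g for g in groups if g.size > 0]
        if len(groups) >= 2 and np.unique(col[obs]).size >= 2:
            if spec.dtype == NUMERICAL:
                if all(np.unique(g).size for g in groups) and \
                        np.concatenate(groups).std() > 0:
                    res = stats.f_oneway(*groups)
                    stat, p = float(res.statistic), float(res.pvalue)
                    if not np.isfinite(p):
                        p = 1.0
            else:
                values = np.unique(col[obs])
                table = np.array([[np.sum(g == val) for val in values] for g in groups])
                table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
                if table.shape[0] >= 2 and table.shape[1] >= 2:
                    chi2 = stats.chi2_contingency(table, correction=False)
                    stat, p = float(chi2[0]), float(chi2[1])
        rows.append({"feature": spec.name, "dtype": spec.dtype,
                     "statistic": stat, "p": p})
    df = pd.DataFrame(rows, columns=["feature", "dtype", "statistic", "p"])
    df["m"] = df.groupby("dtype")["dtype"].transform("size")
    df["threshold"] = alpha / df["m"]
    df["significant"] = df["p"] < df["threshold"]
    return df


# ---------------------------------------------------------------------------
# consensus across views
# ---------------------------------------------------------------------------

def hamming_consensus(solution: CoClusterSolution):
    """Subject x subject Hamming distances across views, with average linkage.

    Entry (i, j) is the fraction of views in which subjects i and j fall in
    different subject clusters. Returns ``(distance_matrix, linkage, newick)``
    where ``newick`` is a nested-parenthesis rendering of the average-linkage
    dendrogram for inspection.
    """
    sc = solution.subject_clusters          # (V, n)
    V, n = sc.shape
    diff = (sc[:, :, None] != sc[:, None, :]).sum(axis=0)
    D = diff / float(V)
    if n < 2:
        return D, None, ";"
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    tree = hierarchy.to_tree(Z)
    ids = solution.subject_ids

    def render(node) -> str:
        if node.is_leaf():
            return ids[node.id]
        left, right = render(node.left), render(node.right)
        return f"({left},{right}):{node.dist:.6g}"

    return D, Z, render(tree) + ";"


# ---------------------------------------------------------------------------
# hyperparameter sensitivity
# ---------------------------------------------------------------------------

def _match_views(base_fv: np.ndarray, other_fv: np.ndarray, n_base: int) -> dict[int, int]:
    match = {}
    for v in range(n_base):
        cols = np.flatnonzero(base_fv == v)
        if cols.size == 0:
            continue
        counts = np.bincount(other_fv[cols])
        match[v] = int(np.argmax(counts))
    return match


def solution_agreement(base: CoClusterSolution, other: CoClusterSolution) -> dict:
    """View-partition and subject-cluster agreement between two solutions.

    ``view_ari`` compares the feature->view partitions. ``subject_ari`` is
    the feature-count-weighted mean, over the baseline's views, of the ARI
    between the baseline subject partition and that of the
    feature-overlap-matched view in the other solution.
    """
    view_ari = adjusted_rand_index(base.feature_view, other.feature_view)
    match = _match_views(base.feature_view, other.feature_view, base.n_views)
    num, den = 0.0, 0.0
    for v, v2 in match.items():
        wgt = float((base.feature_view == v).sum())
        num += wgt * adjusted_rand_index(base.subject_clusters[v],
                                         other.subject_clusters[v2])
        den += wgt
    return {"view_ari": view_ari, "subject_ari": num / den if den else np.nan}


def planted_recovery_scores(solution: CoClusterSolution, truth) -> dict:
    """Agreement of a fitted solution with a planted ground truth.

    ``view_ari`` compares the feature->view partitions. ``subject_aris``
    holds, for every planted view with at least two subject clusters, the
    ARI between the planted partition and the subject partition of the
    fitted view holding most of that view's features (the ARI against a
    single-cluster partition is identically zero by convention, so
    structureless planted views are skipped).
    """
    fv_true = np.asarray(truth.feature_view)
    view_ari = adjusted_rand_index(fv_true, solution.feature_view)
    subject_aris = {}
    for v, part in truth.subject_partitions.items():
        if np.unique(part).size < 2:
            continue
        cols = np.flatnonzero(fv_true == v)
        fitted_v = int(np.bincount(solution.feature_view[cols]).argmax())
        subject_aris[int(v)] = adjusted_rand_index(
            solution.subject_clusters[fitted_v], part)
    return {"view_ari": view_ari, "subject_aris": subject_aris}


def sensitivity_sweep(data: DataMatrix, hp: Hyperparameters,
                      perturbations: Sequence[dict], base_seed: int = 0,
                      n_restarts: int = 5, truncation=(15, 12, 10),
                      tol: float = 1e-6, max_iter: int = 500) -> pd.DataFrame:
    """Refit under perturbed hyperparameters; report agreement with the baseline.

    Each perturbation is a dict of hyperparameter overrides (empty dict =
    baseline settings rerun with the identical seed). One row per grid
    point with the view-partition and subject-cluster ARI vs the baseline.
    """
    if not perturbations:
        raise ValueError("perturbation grid must be nonempty")
    base = fit(data, hp, truncation=truncation, n_restarts=n_restarts,
               base_seed=base_seed, tol=tol, max_iter=max_iter, keep_traces=False)
    rows = []
    for pert in perturbations:
        hp2 = Hyperparameters(**{**hp.as_dict(), **pert})
        sol = fit(data, hp2, truncation=truncation, n_restarts=n_restarts,
                  base_seed=base_seed, tol=tol, max_iter=max_iter, keep_traces=False)
        agree = solution_agreement(base, sol)
        rows.append({"perturbation": repr(pert) if pert else "baseline",
                     **agree, "n_views": sol.n_views})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-view report
# ---------------------------------------------------------------------------

@dataclass
class ViewReport:
    """Characterization statistics for one view of a fitted solution."""

    view: int
    n_features: int
    n_numerical: int
    n_categorical: int
    n_integer: int
    n_subject_clusters: int
    ari_vs_labels: float | None
    proportion_depression_non_fc: float | None
    proportion_depression_all: float | None
    average_cohens_d: float | None
    n_significant: int
    significant_features: list[str]
    pc_scores: np.ndarray | None


def build_view_report(solution: CoClusterSolution, data: DataMatrix,
                      v: int) -> ViewReport:
    cols = solution.view_features(v)
    dtypes = [data.specs[j].dtype for j in cols]
    ari = None
    if data.labels is not None:
        ari = adjusted_rand_index(solution.subject_clusters[v], data.label_array())
    prop = depression_feature_proportion(solution, data, v)
    sig = feature_significance(solution, data, v) if solution.n_subject_clusters(v) >= 2 \
        else pd.DataFrame(columns=["feature", "significant"])
    sig_features = list(sig.loc[sig.get("significant", pd.Series(dtype=bool)) == True,
                                "feature"]) if len(sig) else []
    return ViewReport(
        view=v,
        n_features=int(cols.size),
        n_numerical=dtypes.count(NUMERICAL),
        n_categorical=dtypes.count(CATEGORICAL),
        n_integer=dtypes.count(INTEGER),
        n_subject_clusters=solution.n_subject_clusters(v),
        ari_vs_labels=ari,
        proportion_depression_non_fc=prop["proportion_non_fc"],
        proportion_depression_all=prop["proportion_all"],
        average_cohens_d=average_cohens_d(solution, data, v),
        n_significant=len(sig_features),
        significant_features=sig_features,
        pc_scores=view_fc_pc_scores(solution, data, v),
    )


def view_report_table(solution: CoClusterSolution, data: DataMatrix) -> pd.DataFrame:
    """One row per view of summary statistics (PC score vectors omitted)."""
    rows = []
    for v in range(solution.n_views):
        rep = build_view_report(solution, data, v)
        rows.append({k: getattr(rep, k) for k in
                     ("view", "n_features", "n_numerical", "n_categorical",
                      "n_integer", "n_subject_clusters", "ari_vs_labels",
                      "proportion_depression_non_fc", "proportion_depression_all",
                      "average_cohens_d", "n_significant")})
    return pd.DataFrame(rows)
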