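"""Depression-subtype prediction from reduced predictor sets.

Two predictors suffice for the three depressed subtypes: a functional-
connectivity score (first principal component of the angular-gyrus-related
FC feature cluster) and a childhood-trauma (CATS) score. The package
provides

* leave-one-out classification with supervised Gaussian mixture components
  (class-conditional Gaussians re-estimated from the remaining subjects'
  known memberships), evaluated over incremental predictor sets; and
* a two-step threshold classifier: low FC score -> D3, otherwise low CATS
  -> D2, otherwise D1, with the outcome map D1 -> treatment-resistant,
  D2/D3 -> responsive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SUBTYPES = ("D1", "D2", "D3")
OUTCOME_MAP = {"D1": "resistant", "D2": "responsive", "D3": "responsive"}
UNCLASSIFIABLE = "unclassifiable"

__all__ = [
    "SubtypeClassifier",
    "LoocvResult",
    "loocv_gmm_accuracy",
    "loocv_curve",
    "fit_threshold_classifier",
    "classify_subject",
    "classify_many",
    "characterize_clusters",
    "name_depressed_clusters",
    "SUBTYPES",
    "OUTCOME_MAP",
    "UNCLASSIFIABLE",
]


# ---------------------------------------------------------------------------
# leave-one-out supervised Gaussian-mixture classification
# ---------------------------------------------------------------------------

@dataclass
class LoocvResult:
    """Outcome of one leave-one-out run for a named predictor set."""

    label: str
    predicted: list[str]
    true: list[str]
    proportion_correct: float
    n_jittered: int = 0


def _class_gaussians(X: np.ndarray, y: np.ndarray, ridge: float):
    """Supervised class-conditional Gaussians (ML mean/cov + mixing weights).

    Singular covariances are ridge-regularized by adding multiples of
    ``ridge * mean-variance`` to the diagonal until the matrix is positive
    definite; the number of jitter applications is returned.
    """
    classes = np.unique(y)
    params = {}
    n_jittered = 0
    p = X.shape[1]
    for c in classes:
        sub = X[y == c]
        mu = sub.mean(axis=0)
        cov = np.cov(sub, rowvar=False, ddof=0).reshape(p, p)
        scale = max(np.trace(cov) / p, 1e-12)
        jitter = 0.0
        while True:
            try:
                chol = np.linalg.cholesky(cov + jitter * np.eye(p))
                break
            except np.linalg.LinAlgError:
                n_jittered += 1
                jitter = ridge * scale if jitter == 0 else jitter * 10.0
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        params[c] = (mu, chol, logdet, np.log(sub.shape[0] / X.shape[0]))
    return params, n_jittered


def _log_posteriors(x: np.ndarray, params) -> dict:
    out = {}
    p = x.size
    for c, (mu, chol, logdet, logprior) in params.items():
        sol = np.linalg.solve(chol, x - mu)
        maha = float(sol @ sol)
        out[c] = logprior - 0.5 * (maha + logdet + p * np.log(2 * np.pi))
    return out


def loocv_gmm_accuracy(predictors: np.ndarray, memberships, label: str = "",
                       ridge: float = 1e-6) -> LoocvResult:
    """Leave-one-out membership prediction with supervised Gaussian components.

    For each subject: hold out, re-estimate per-cluster Gaussian means, full
    covariances and mixing weights from the remaining subjects' known
    memberships, and assign the held-out subject to the maximum-posterior
    component. Requires >= 2 clusters with >= 2 members each.
    """
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] == 1 and np.asarray(memberships).size > 1:
        X = X.T
    y = np.asarray(memberships)
    if X.shape[0] != y.size:
        raise ValueError("predictors and memberships must align")
    if np.isnan(X).any():
        raise ValueError("predictors must be complete (no missing values)")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("need >= 2 clusters with >= 2 members each")
    predicted = []
    n_jittered = 0
    for i in range(X.shape[0]):
        keep = np.ones(X.shape[0], dtype=bool)
        keep[i] = False
        params, nj = _class_gaussians(X[keep], y[keep], ridge)
        n_jittered += nj
        logpost = _log_posteriors(X[i], params)
        # deterministic tie-break: lexicographically first class among maxima
        best = max(sorted(logpost), key=lambda c: (logpost[c],))
        predicted.append(best)
    correct = float(np.mean([p == t for p, t in zip(predicted, y)]))
    return LoocvResult(label=label, predicted=[str(p) for p in predicted],
                       true=[str(t) for t in y], proportion_correct=correct,
                       n_jittered=n_jittered)


def loocv_curve(predictor_sets: dict[str, np.ndarray], memberships) -> list[LoocvResult]:
    """One LOOCV accuracy per named (typically incremental) predictor set."""
    return [loocv_gmm_accuracy(X, memberships, label=label)
            for label, X in predictor_sets.items()]


# ---------------------------------------------------------------------------
# two-step threshold classifier
# ---------------------------------------------------------------------------

@dataclass
class SubtypeClassifier:
    """Two learned thresholds and the fixed subtype/outcome maps.

    ``fc_threshold`` separates D3 (below) from D1/D2; ``cats_threshold``
    separates D2 (below) from D1 among non-D3 subjects. D1 maps to
    treatment-resistant, D2 and D3 to responsive.
    """

    fc_threshold: float
    cats_threshold: float
    outcome_map: dict[str, str] = field(default_factory=lambda: dict(OUTCOME_MAP))
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fc_threshold": self.fc_threshold,
            "cats_threshold": self.cats_threshold,
            "rule": "fc < fc_threshold -> D3; else cats < cats_threshold -> D2; else D1",
            "outcome_map": self.outcome_map,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SubtypeClassifier":
        payload = json.loads(Path(path).read_text())
        return cls(fc_threshold=float(payload["fc_threshold"]),
                   cats_threshold=float(payload["cats_threshold"]),
                   outcome_map=dict(payload.get("outcome_map", OUTCOME_MAP)),
                   provenance=dict(payload.get("provenance", {})))


def _best_threshold(scores: np.ndarray, below_mask: np.ndarray) -> float:
    """Midpoint threshold maximizing accuracy of (score < t) == below_mask.

    Candidates are midpoints between consecutive sorted unique scores; ties
    are broken toward the lower threshold.
    """
    uniq = np.unique(scores)
    if uniq.size < 2:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:
        acc = float(np.mean((scores < t) == below_mask))
        if acc > best_acc:
            best_t, best_acc = t, acc
    return float(best_t)


def fit_threshold_classifier(fc_scores, cats_scores, memberships,
                             provenance: dict | None = None) -> SubtypeClassifier:
    """Learn the two thresholds by resubstitution accuracy maximization.

    The FC threshold maximizes D3-vs-rest accuracy over midpoints between
    sorted unique FC scores; the CATS threshold then maximizes D1-vs-D2
    accuracy among the true non-D3 subjects.
    """
    fc = np.asarray(fc_scores, dtype=float)
    cats = np.asarray(cats_scores, dtype=float)
    y = np.asarray([str(m) for m in memberships])
    for s in SUBTYPES:
        if not np.any(y == s):
            raise ValueError(f"cluster {s} is not represented")
    fc_thr = _best_threshold(fc, y == "D3")
    non_d3 = y != "D3"
    cats_thr = _best_threshold(cats[non_d3], y[non_d3] == "D2")
    return SubtypeClassifier(fc_threshold=fc_thr, cats_threshold=cats_thr,
                             provenance=provenance or {})


def classify_subject(clf: SubtypeClassifier, fc_score: float,
                     cats_score: float) -> tuple[str, str]:
    """Apply the two-step rule; returns (subtype, outcome label).

    A missing FC score is unclassifiable; a missing CATS score is
    unclassifiable unless the FC score already settles D3.
    """
    if fc_score is None or np.isnan(fc_score):
        return (UNCLASSIFIABLE, UNCLASSIFIABLE)
    if fc_score < clf.fc_threshold:
        return ("D3", clf.outcome_map["D3"])
    if cats_score is None or np.isnan(cats_score):
        return (UNCLASSIFIABLE, UNCLASSIFIABLE)
    if cats_score < clf.cats_threshold:
        return ("D2", clf.outcome_map["D2"])
    return ("D1", clf.outcome_map["D1"])


def classify_many(clf: SubtypeClassifier, fc_scores, cats_scores) -> pd.DataFrame:
    fc = np.asarray(fc_scores, dtype=float)
    cats = np.asarray(cats_scores, dtype=float)
    rows = [classify_subject(clf, f, c) for f, c in zip(fc, cats)]
    return pd.DataFrame(rows, columns=["subtype", "outcome"])


# ---------------------------------------------------------------------------
# cluster profiles
# ---------------------------------------------------------------------------

def characterize_clusters(X: np.ndarray, memberships, feature_names) -> pd.DataFrame:
    """Per-cluster mean/sd with high/moderate/low tags vs pooled terciles.

    Tercile boundaries are the 1/3 and 2/3 quantiles of each feature over
    all provided subjects (the depressed group, by convention); a cluster is
    tagged ``low``/``high`` when its mean falls below/above the boundaries,
    else ``moderate``. Missing entries are ignored per feature.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(m) for m in memberships])
    rows = []
    for jj, name in enumerate(feature_names):
        col = X[:, jj]
        obs = ~np.isnan(col)
        lo, hi = np.quantile(col[obs], [1.0 / 3.0, 2.0 / 3.0])
        for c in sorted(set(y)):
            vals = col[(y == c) & obs]
            mean = float(vals.mean()) if vals.size else np.nan
            sd = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
            tag = "moderate"
            if mean < lo:
                tag = "low"
            elif mean > hi:
                tag = "high"
            rows.append({"cluster": c, "feature": name, "mean": mean,
                         "sd": sd, "tag": tag})
    return pd.DataFrame(rows, columns=["cluster", "feature", "mean", "sd", "tag"])


def name_depressed_clusters(fc_scores, cats_scores, memberships) -> dict:
    """Map three anonymous depressed clusters onto D1/D2/D3 by their profile.

    D3 is the cluster with the lowest mean FC score; of the remaining two,
    D1 has the higher mean CATS score.
    """
    fc = np.asarray(fc_scores, dtype=float)
    cats = np.asarray(cats_scores, dtype=float)
    y = np.asarray(memberships)
    clusters = sorted(set(y.tolist()))
    if len(clusters) != 3:
        raise ValueError(f"expected exactly 3 depressed clusters, got {len(clusters)}")
    fc_means = {c: float(np.nanmean(fc[y == c])) for c in clusters}
    d3 = min(clusters, key=lambda c: fc_means[c])
    rest = [c for c in clusters if c != d3]
    cats_means = {c: float(np.nanmean(cats[y == c])) for c in rest}
    d1 = max(rest, key=lambda c: cats_means[c])
    d2 = [c for c in rest if c != d1][0]
    return {d1: "D1", d2: "D2", d3: "D3"}
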