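"""Tabular study data: mixed-type data matrices, FC feature computation, standardization, I/O.

The central container is :class:`DataMatrix`, a subjects x features table of
mixed-type values (numerical, categorical, integer) with missing entries,
carried as a float array in which ``NaN`` marks a missing cell. Categorical
values are stored as non-negative integer level codes with the level list
declared in the per-column :class:`FeatureSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NUMERICAL = "numerical"
CATEGORICAL = "categorical"
INTEGER = "integer"
DTYPES = (NUMERICAL, CATEGORICAL, INTEGER)

GROUP_FC = "FC"
GROUP_QUESTIONNAIRE = "questionnaire"
GROUP_BIOLOGICAL = "biological"
GROUPS = (GROUP_FC, GROUP_QUESTIONNAIRE, GROUP_BIOLOGICAL)


@dataclass(frozen=True)
class FeatureSpec:
    """Declared identity, type, and provenance of one column.

    Parameters
    ----------
    name :
        Column identifier, unique within a matrix.
    dtype :
        One of ``numerical`` (Gaussian blocks), ``categorical`` (level
        codes, Dirichlet blocks) or ``integer`` (counts, Poisson blocks).
    levels :
        Ordered level labels, categorical columns only (>= 2 required).
        Observed values are codes ``0 .. len(levels)-1``.
    group :
        ``FC`` for functional-connectivity features, else ``questionnaire``
        or ``biological``. FC features must be numerical.
    depression_related :
        Whether the feature counts as depression-related in view reports
        (clinical questionnaire items; never FC features).
    """

    name: str
    dtype: str
    levels: tuple[str, ...] | None = None
    group: str = GROUP_QUESTIONNAIRE
    depression_related: bool = False

    def __post_init__(self) -> None:
        if self.dtype not in DTYPES:
            raise ValueError(f"feature {self.name!r}: unknown dtype {self.dtype!r}")
        if self.group not in GROUPS:
            raise ValueError(f"feature {self.name!r}: unknown group {self.group!r}")
        if self.dtype == CATEGORICAL:
            if self.levels is None or len(self.levels) < 2:
                raise ValueError(
                    f"categorical feature {self.name!r} must declare >= 2 levels"
                )
        elif self.levels is not None:
            raise ValueError(f"feature {self.name!r}: levels only valid for categorical")
        if self.group == GROUP_FC and self.dtype != NUMERICAL:
            raise ValueError(f"FC feature {self.name!r} must be numerical")

    @property
    def n_levels(self) -> int:
        return 0 if self.levels is None else len(self.levels)


@dataclass
class DataMatrix:
    """Subjects x features values with missing mask and per-column metadata.

    ``values`` is float with NaN for missing entries; ``observed`` gives the
    boolean mask. ``labels`` optionally maps each subject to
    ``control``/``depressed``.
    """

    values: np.ndarray
    subject_ids: list[str]
    specs: list[FeatureSpec]
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x features)")
        n, d = self.values.shape
        if len(self.subject_ids) != n:
            raise ValueError(f"{len(self.subject_ids)} subject ids for {n} rows")
        if len(self.specs) != d:
            raise ValueError(f"{len(self.specs)} specs for {d} columns")
        names = [s.name for s in self.specs]
        if len(set(names)) != d:
            raise ValueError("duplicate feature names")
        if self.labels is not None:
            missing = [s for s in self.subject_ids if s not in self.labels]
            if missing:
                raise ValueError(f"labels missing for subjects {missing[:5]}")
        self.validate_values()

    # -- basic accessors ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask, True where a value is present."""
        return ~np.isnan(self.values)

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def dtype_indices(self, dtype: str) -> np.ndarray:
        return np.array([j for j, s in enumerate(self.specs) if s.dtype == dtype], dtype=int)

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([j for j, s in enumerate(self.specs) if s.group == group], dtype=int)

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("matrix carries no subject labels")
        return np.array([self.labels[s] for s in self.subject_ids])

    def validate_values(self) -> None:
        """Check observed entries against the declared column types."""
        for j, spec in enumerate(self.specs):
            col = self.values[:, j]
            obs = col[~np.isnan(col)]
            if spec.dtype == CATEGORICAL:
                bad = (obs != np.round(obs)) | (obs < 0) | (obs >= spec.n_levels)
                if bad.any():
                    i = int(np.flatnonzero(~np.isnan(col))[np.flatnonzero(bad)[0]])
                    raise ValueError(
                        f"feature {spec.name!r}, subject {self.subject_ids[i]!r}: "
                        f"value {col[i]} outside declared levels"
                    )
            elif spec.dtype == INTEGER:
                bad = (obs != np.round(obs)) | (obs < 0)
                if bad.any():
                    i = int(np.flatnonzero(~np.isnan(col))[np.flatnonzero(bad)[0]])
                    raise ValueError(
                        f"feature {spec.name!r}, subject {self.subject_ids[i]!r}: "
                        f"value {col[i]} is not a non-negative integer"
                    )

    def copy(self) -> "DataMatrix":
        return DataMatrix(
            self.values.copy(),
            list(self.subject_ids),
            list(self.specs),
            None if self.labels is None else dict(self.labels),
        )


@dataclass
class RoiTimeSeriesSet:
    """Per-subject ROI x time BOLD-average tables over a shared ROI list."""

    roi_names: list[str]
    series: dict[str, np.ndarray]  # subject id -> (n_rois, T)

    def __post_init__(self) -> None:
        n = len(self.roi_names)
        for sid, ts in self.series.items():
            ts = np.asarray(ts, dtype=float)
            if ts.ndim != 2 or ts.shape[0] != n:
                raise ValueError(f"subject {sid!r}: series must be ({n}, T)")
            if ts.shape[1] < 3:
                raise ValueError(f"subject {sid!r}: series length must be >= 3")
            self.series[sid] = ts

    @property
    def subject_ids(self) -> list[str]:
        return list(self.series)


def fc_pair_names(roi_names: Sequence[str]) -> list[str]:
    """Feature names ``<roiA>__<roiB>``, row-major over the strict upper triangle."""
    n = len(roi_names)
    return [f"{roi_names[a]}__{roi_names[b]}" for a in range(n) for b in range(a + 1, n)]


def compute_fc_features(ts: RoiTimeSeriesSet) -> DataMatrix:
    """Pairwise-correlation FC features from ROI-averaged time series.

    Functional connectivity between two ROIs is the Pearson correlation of
    their average BOLD time series. One numerical feature per unordered ROI
    pair; with ``n`` ROIs that is ``n*(n-1)/2`` features, ordered row-major
    over the strict upper triangle of the correlation matrix.
    """
    n = len(ts.roi_names)
    iu = np.triu_indices(n, k=1)
    rows = []
    for sid in ts.subject_ids:
        mat = ts.series[sid]
        sd = mat.std(axis=1)
        if np.any(sd == 0):
            roi = ts.roi_names[int(np.flatnonzero(sd == 0)[0])]
            raise ValueError(f"ROI {roi!r} has zero-variance series for subject {sid!r}")
        rows.append(np.corrcoef(mat)[iu])
    specs = [FeatureSpec(name, NUMERICAL, group=GROUP_FC) for name in fc_pair_names(ts.roi_names)]
    return DataMatrix(np.vstack(rows), ts.subject_ids, specs)


def standardize_features(data: DataMatrix, fc_reference_ids: Iterable[str]) -> DataMatrix:
    """Standardize numerical features; categorical/integer pass through.

    FC features are centred and scaled by the mean and standard deviation of
    the reference (control) subjects, so the control group sets the baseline.
    All other numerical features are standardized over all subjects. Means
    and standard deviations ignore missing entries; the missing mask is
    unchanged. The standard deviation uses the population (ddof=0)
    denominator, so two reference values {1, 3} map exactly to {-1, +1}.
    """
    ref_ids = list(fc_reference_ids)
    id_to_row = {s: i for i, s in enumerate(data.subject_ids)}
    unknown = [s for s in ref_ids if s not in id_to_row]
    if unknown:
        raise ValueError(f"unknown reference subjects {unknown[:5]}")
    ref_rows = np.array([id_to_row[s] for s in ref_ids], dtype=int)

    out = data.values.copy()
    for j, spec in enumerate(data.specs):
        if spec.dtype != NUMERICAL:
            continue
        col = out[:, j]
        sub = col[ref_rows] if spec.group == GROUP_FC else col
        obs = sub[~np.isnan(sub)]
        if obs.size < 2:
            raise ValueError(f"feature {spec.name!r}: fewer than 2 observed values for standardization")
        mu, sd = obs.mean(), obs.std(ddof=0)
        if sd == 0:
            raise ValueError(f"feature {spec.name!r}: zero spread, cannot standardize")
        out[:, j] = (col - mu) / sd
    return DataMatrix(out, list(data.subject_ids), list(data.specs),
                      None if data.labels is None else dict(data.labels))


# -- TSV / sidecar I/O -----------------------------------------------------

def write_data(data: DataMatrix, matrix_path: str | Path, sidecar_path: str | Path,
               labels_path: str | Path | None = None) -> None:
    """Write matrix TSV (subjects as rows; empty cell = missing) + type sidecar."""
    matrix_path, sidecar_path = Path(matrix_path), Path(sidecar_path)
    df = pd.DataFrame(data.values, index=data.subject_ids, columns=data.feature_names)
    # integer-valued columns print without a trailing .0
    for j, spec in enumerate(data.specs):
        if spec.dtype in (CATEGORICAL, INTEGER):
            df[spec.name] = df[spec.name].astype("Int64")
    df.to_csv(matrix_path, sep="\t", index_label="subject", na_rep="")
    side = pd.DataFrame(
        {
            "feature": data.feature_names,
            "dtype": [s.dtype for s in data.specs],
            "levels": [";".join(s.levels) if s.levels else "" for s in data.specs],
            "group": [s.group for s in data.specs],
            "depression_related": [int(s.depression_related) for s in data.specs],
        }
    )
    side.to_csv(sidecar_path, sep="\t", index=False)
    if labels_path is not None:
        if data.labels is None:
            raise ValueError("matrix carries no labels to write")
        pd.DataFrame(
            {"subject": data.subject_ids,
             "label": [data.labels[s] for s in data.subject_ids]}
        ).to_csv(labels_path, sep="\t", index=False)


def read_data(matrix_path: str | Path, sidecar_path: str | Path,
              labels_path: str | Path | None = None) -> DataMatrix:
    """Read a matrix TSV plus sidecar (and optional labels) back into a DataMatrix."""
    side = pd.read_csv(sidecar_path, sep="\t", dtype=str).fillna("")
    required = {"feature", "dtype", "group"}
    if not required.issubset(side.columns):
        raise ValueError(f"sidecar {sidecar_path} lacks columns {sorted(required - set(side.columns))}")
    specs = {}
    for _, row in side.iterrows():
        levels = tuple(row.get("levels", "").split(";")) if row.get("levels", "") else None
        specs[row["feature"]] = FeatureSpec(
            row["feature"], row["dtype"], levels=levels, group=row["group"],
            depression_related=bool(int(row.get("depression_related", "0") or 0)),
        )
    df = pd.read_csv(matrix_path, sep="\t", index_col="subject")
    df.index = df.index.astype(str)
    missing_cols = [c for c in df.columns if c not in specs]
    if missing_cols:
        raise ValueError(f"sidecar missing feature(s) {missing_cols[:5]}")
    ordered = [specs[c] for c in df.columns]
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", dtype=str)
        labels = dict(zip(lab["subject"], lab["label"]))
    return DataMatrix(df.to_numpy(dtype=float), [str(s) for s in df.index], ordered, labels)


def write_solution(solution, out_dir: str | Path) -> None:
    """Persist a fitted co-clustering solution as per-view TSVs plus a JSON manifest.

    One TSV per view listing (feature, feature cluster); one TSV of
    (subject, view, subject cluster); ``manifest.json`` with hyperparameters,
    truncation, seeds, scores and restart log.
    """
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for v in range(solution.n_views):
        idx = np.flatnonzero(solution.feature_view == v)
        pd.DataFrame(
            {"feature": [solution.feature_names[j] for j in idx],
             "feature_cluster": [solution.feature_cluster_label(j) for j in idx]}
        ).to_csv(out / f"view{v + 1}_features.tsv", sep="\t", index=False)
    rows = []
    for v in range(solution.n_views):
        for i, sid in enumerate(solution.subject_ids):
            rows.append((sid, v + 1, int(solution.subject_clusters[v, i]) + 1))
    pd.DataFrame(rows, columns=["subject", "view", "subject_cluster"]).to_csv(
        out / "subject_clusters.tsv", sep="\t", index=False
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(solution.manifest(), fh, indent=2, sort_keys=True)


def read_solution_assignments(out_dir: str | Path):
    """Read back the assignment TSVs written by :func:`write_solution`.

    Returns ``(feature_view, feature_cluster_label, subject_clusters)`` as
    plain dict/array structures; used for round-trip checks and downstream
    tooling, not to reconstruct block posteriors.
    """
    out = Path(out_dir)
    feature_view: dict[str, int] = {}
    feature_cluster: dict[str, str] = {}
    v = 1
    while (out / f"view{v}_features.tsv").exists():
        df = pd.read_csv(out / f"view{v}_features.tsv", sep="\t", dtype=str)
        for _, row in df.iterrows():
            feature_view[row["feature"]] = v - 1
            feature_cluster[row["feature"]] = row["feature_cluster"]
        v += 1
    sc = pd.read_csv(out / "subject_clusters.tsv", sep="\t")
    sc["subject"] = sc["subject"].astype(str)
    subjects = list(dict.fromkeys(sc["subject"]))
    n_views = int(sc["view"].max())
    arr = np.zeros((n_views, len(subjects)), dtype=int)
    pos = {s: i for i, s in enumerate(subjects)}
    for _, row in sc.iterrows():
        arr[int(row["view"]) - 1, pos[row["subject"]]] = int(row["subject_cluster"]) - 1
    return feature_view, feature_cluster, subjects, arr
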