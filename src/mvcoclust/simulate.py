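"""Synthetic mixed-type data with planted multi-view co-cluster structure.

Three generators, all deterministic under a fixed seed:

* :func:`simulate_planted` draws a :class:`~mvcoclust.data.DataMatrix` from a
  fully specified :class:`PlantedStructure` (block distributions per view x
  feature cluster x subject cluster) and returns the ground truth at all
  three levels.
* :func:`simulate_roi_timeseries` draws ROI-averaged BOLD-like series with a
  prescribed population correlation matrix.
* :func:`simulate_depression_study` builds a full case/control study-like
  fixture: FC-style numerical features standardized to a control baseline,
  questionnaire scores, categorical/SNP-like items and integer counts, with
  a diagnosis-linked view whose depressed subject clusters follow a
  D1/D2/D3 profile (D1: high childhood-trauma score, high FC score, poor
  treatment outcome; D2: low trauma, moderate FC, good outcome; D3: low FC,
  high baseline severity, high trauma, good outcome), one
  nuisance-demographic view, and one structureless noise view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (CATEGORICAL, GROUP_BIOLOGICAL, GROUP_FC, GROUP_QUESTIONNAIRE,
                   INTEGER, NUMERICAL, DataMatrix, FeatureSpec, RoiTimeSeriesSet)

__all__ = [
    "Block",
    "PlantedStructure",
    "PlantedTruth",
    "StudyFixtureConfig",
    "StudyFixture",
    "simulate_planted",
    "simulate_roi_timeseries",
    "simulate_roi_timeseries_set",
    "simulate_depression_study",
    "simulate_recovery_benchmark",
    "write_ground_truth",
]


@dataclass(frozen=True)
class Block:
    """Distribution of one planted block: Gaussian, categorical or Poisson."""

    kind: str
    mean: float = 0.0
    sd: float = 1.0
    probs: tuple[float, ...] | None = None
    rate: float = 0.0

    @classmethod
    def gaussian(cls, mean: float, sd: float = 1.0) -> "Block":
        return cls(NUMERICAL, mean=mean, sd=sd)

    @classmethod
    def categorical(cls, probs: Sequence[float]) -> "Block":
        return cls(CATEGORICAL, probs=tuple(float(p) for p in probs))

    @classmethod
    def poisson(cls, rate: float) -> "Block":
        return cls(INTEGER, rate=float(rate))

    def validate(self) -> None:
        if self.kind == NUMERICAL:
            if not self.sd > 0:
                raise ValueError(f"Gaussian block sd must be > 0, got {self.sd}")
        elif self.kind == CATEGORICAL:
            if self.probs is None or any(p < 0 for p in self.probs) \
                    or abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValueError(f"invalid probability vector {self.probs}")
        elif self.kind == INTEGER:
            if self.rate < 0:
                raise ValueError(f"Poisson rate must be >= 0, got {self.rate}")
        else:
            raise ValueError(f"unknown block kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == NUMERICAL:
            return rng.normal(self.mean, self.sd, size)
        if self.kind == CATEGORICAL:
            return rng.choice(len(self.probs), size=size, p=self.probs).astype(float)
        return rng.poisson(self.rate, size).astype(float)


@dataclass
class PlantedStructure:
    """Full generative specification of a planted multi-view dataset.

    ``features`` lists (view id, feature type, feature-cluster id) per
    column; ``subject_partitions`` maps each view id to a length-n cluster
    vector; ``blocks`` maps (view, feature cluster, subject cluster) to a
    :class:`Block` whose kind matches the features assigned there.
    """

    n_subjects: int
    features: list[tuple[int, str, int]]
    subject_partitions: dict[int, np.ndarray]
    blocks: dict[tuple[int, int, int], Block]
    missing_rate: float = 0.0
    seed: int = 0
    feature_names: list[str] | None = None
    specs: list[FeatureSpec] | None = None

    def validate(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for blk in self.blocks.values():
            blk.validate()
        for v, part in self.subject_partitions.items():
            if len(part) != self.n_subjects:
                raise ValueError(f"partition of view {v} has wrong length")
        for j, (v, dtype, g) in enumerate(self.features):
            if v not in self.subject_partitions:
                raise ValueError(f"feature {j}: view {v} has no subject partition")
            for k in np.unique(self.subject_partitions[v]):
                key = (v, g, int(k))
                if key not in self.blocks:
                    raise ValueError(f"no block distribution for {key}")
                if self.blocks[key].kind != dtype:
                    raise ValueError(f"block {key} kind mismatches feature type {dtype}")


@dataclass
class PlantedTruth:
    """Ground-truth labels at all three levels of the partition."""

    feature_view: np.ndarray
    feature_cluster: np.ndarray
    subject_partitions: dict[int, np.ndarray]


def _default_specs(structure: PlantedStructure) -> list[FeatureSpec]:
    specs = []
    for j, (v, dtype, g) in enumerate(structure.features):
        name = (structure.feature_names[j] if structure.feature_names
                else f"f{j + 1:04d}")
        if dtype == CATEGORICAL:
            n_levels = max(len(structure.blocks[key].probs)
                           for key in structure.blocks
                           if key[0] == v and key[1] == g)
            levels = tuple(f"l{i}" for i in range(n_levels))
            specs.append(FeatureSpec(name, dtype, levels=levels))
        else:
            specs.append(FeatureSpec(name, dtype))
    return specs


def simulate_planted(structure: PlantedStructure) -> tuple[DataMatrix, PlantedTruth]:
    """Draw a data matrix cell-wise i.i.d. from the planted block distributions.

    The missing mask is Bernoulli(``missing_rate``) independently per cell.
    """
    structure.validate()
    rng = np.random.default_rng(structure.seed)
    n = structure.n_subjects
    d = len(structure.features)
    values = np.empty((n, d))
    for j, (v, dtype, g) in enumerate(structure.features):
        part = structure.subject_partitions[v]
        col = np.empty(n)
        for k in np.unique(part):
            rows = np.flatnonzero(part == k)
            col[rows] = structure.blocks[(v, g, int(k))].sample(rng, rows.size)
        values[:, j] = col
    if structure.missing_rate > 0:
        values[rng.random((n, d)) < structure.missing_rate] = np.nan
    specs = structure.specs if structure.specs is not None else _default_specs(structure)
    subject_ids = [f"s{i + 1:04d}" for i in range(n)]
    data = DataMatrix(values, subject_ids, specs)
    truth = PlantedTruth(
        feature_view=np.array([f[0] for f in structure.features]),
        feature_cluster=np.array([f[2] for f in structure.features]),
        subject_partitions={v: np.asarray(p) for v, p in structure.subject_partitions.items()},
    )
    return data, truth


# ---------------------------------------------------------------------------
# ROI time series
# ---------------------------------------------------------------------------

def simulate_roi_timeseries(n_rois: int, series_length: int,
                            target_corr: np.ndarray, seed: int = 0) -> np.ndarray:
    """Zero-mean ROI x time series whose population correlation is ``target_corr``.

    The target must be symmetric positive semi-definite with unit diagonal.
    """
    C = np.asarray(target_corr, dtype=float)
    if C.shape != (n_rois, n_rois):
        raise ValueError(f"target matrix must be {n_rois}x{n_rois}")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("target correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValueError("target correlation matrix must have unit diagonal")
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-8:
        raise ValueError(f"target correlation matrix is not PSD (min eigenvalue {w.min():.3g})")
    A = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    return A @ rng.standard_normal((n_rois, series_length))


def simulate_roi_timeseries_set(subject_ids: Sequence[str], roi_names: Sequence[str],
                                series_length: int, target_corr: np.ndarray,
                                seed: int = 0) -> RoiTimeSeriesSet:
    """One :func:`simulate_roi_timeseries` draw per subject, shared target."""
    series = {}
    for i, sid in enumerate(subject_ids):
        series[sid] = simulate_roi_timeseries(len(roi_names), series_length,
                                              target_corr, seed=seed + i)
    return RoiTimeSeriesSet(list(roi_names), series)


# ---------------------------------------------------------------------------
# depression-study fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyFixtureConfig:
    """Conditions of the study-like fixture.

    Defaults mirror a 67/67 case-control design with an FC feature block of
    2701 pairwise correlations and a reduced questionnaire battery.
    ``effect_size`` is the planted between-cluster separation of the
    depressed subtypes in block-sd units; at 0 the D1/D2/D3 profiles
    coincide.
    """

    n_control: int = 67
    n_depressed: int = 67
    n_fc_features: int = 2701
    n_questionnaire_features: int = 40
    n_categorical: int = 20
    n_integer: int = 2
    effect_size: float = 3.0
    outcome_noise_sd: float = 0.5
    missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_control", "n_depressed", "n_fc_features",
                     "n_questionnaire_features", "n_categorical", "n_integer"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_depressed and self.n_depressed < 12:
            raise ValueError("need >= 12 depressed subjects for three subtypes")
        if self.n_fc_features < 6:
            raise ValueError("need >= 6 FC features")
        if self.n_questionnaire_features < 11:
            raise ValueError("need >= 11 questionnaire features (CATS/severity/outcome blocks)")
        if self.n_categorical < 2:
            raise ValueError("need >= 2 categorical features (sex, remission)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.outcome_noise_sd <= 0:
            raise ValueError("outcome_noise_sd must be > 0")


@dataclass
class StudyFixture:
    """A simulated study: data, labels, outcome scores and planted truth."""

    data: DataMatrix
    truth: PlantedTruth
    subtype: dict[str, str]          # depressed subject -> D1/D2/D3
    cluster_names: list[str]         # diagnosis-view cluster id -> name
    outcome: dict[str, float]        # depressed subject -> post-treatment score
    config: StudyFixtureConfig

    @property
    def diagnosis_view(self) -> int:
        return 0

    def depressed_ids(self) -> list[str]:
        return [s for s in self.data.subject_ids
                if self.data.labels is not None and self.data.labels[s] == "depressed"]

    def ag_fc_feature_indices(self) -> np.ndarray:
        """Columns of the planted AG-related FC feature cluster (view 0, cluster 0)."""
        return np.flatnonzero((self.truth.feature_view == 0)
                              & (self.truth.feature_cluster == 0))

    def cats_feature_index(self) -> int:
        return self.data.feature_names.index("CATS_total")


# planted profile of the diagnosis view, one row per subject cluster
# [C1, C2, D1, D2, D3]; entries scaled by the effect size e where marked
def _diagnosis_profile(e: float) -> dict[str, list[float]]:
    return {
        # AG-related FC score: D1 high, D2 moderate, D3 low
        "ag_fc": [0.0, 0.0, e, 0.0, -e],
        # secondary FC cluster separating the two control clusters
        "sec_fc": [1.0, -1.0, 0.5 * e, 0.0, -0.5 * e],
        # childhood-trauma scores: high in D1 and D3
        "cats": [0.0, 0.0, e, 0.0, e],
        # baseline severity: depressed above controls, D3 highest
        "severity": [-1.0, -1.0, 0.5, 0.5, 0.5 + e],
        # post-treatment severity: high (treatment-resistant) only in D1
        "outcome": [-0.5, -0.5, e, 0.0, 0.0],
    }


def simulate_depression_study(config: StudyFixtureConfig | None = None) -> StudyFixture:
    """Simulate a case-control fixture with planted D1/D2/D3 structure.

    Three views are planted: view 0 carries the diagnosis-linked structure
    (5 subject clusters: C1, C2, D1, D2, D3), view 1 a demographic nuisance
    split independent of diagnosis, and view 2 structureless noise. Missing
    entries are missing-completely-at-random on non-FC features.
    """
    config = config or StudyFixtureConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    e = float(config.effect_size)
    n_ctrl, n_dep = config.n_control, config.n_depressed
    n = n_ctrl + n_dep
    subject_ids = ([f"ctrl{i + 1:03d}" for i in range(n_ctrl)]
                   + [f"dep{i + 1:03d}" for i in range(n_dep)])
    labels = {s: ("control" if s.startswith("ctrl") else "depressed") for s in subject_ids}

    # diagnosis-view partition: C1/C2 split controls, D1/D2/D3 split depressed
    diag = np.empty(n, dtype=int)
    ctrl_perm = rng.permutation(n_ctrl)
    diag[:n_ctrl] = np.where(ctrl_perm < (n_ctrl + 1) // 2, 0, 1)
    dep_perm = rng.permutation(n_dep)
    diag[n_ctrl:] = 2 + dep_perm * 3 // n_dep
    # nuisance partition: random half/half, independent of diagnosis
    nuis = (rng.permutation(n) < n // 2).astype(int)
    noise = np.zeros(n, dtype=int)

    profile = _diagnosis_profile(e)
    features: list[tuple[int, str, int]] = []
    names: list[str] = []
    specs: list[FeatureSpec] = []
    blocks: dict[tuple[int, int, int], Block] = {}

    def add_numeric_cluster(view: int, fcid: int, base: str, count: int,
                            means_by_cluster: list[float], group: str,
                            flagged: bool, sd: float = 1.0) -> None:
        for i in range(count):
            name = base if count == 1 else f"{base}_{i + 1}" if not base.startswith("FC") \
                else f"{base}{i + 1:04d}"
            features.append((view, NUMERICAL, fcid))
            names.append(name)
            specs.append(FeatureSpec(name, NUMERICAL, group=group,
                                     depression_related=flagged))
        for k, mu in enumerate(means_by_cluster):
            blocks[(view, fcid, k)] = Block.gaussian(mu, sd)

    # ---- view 0: diagnosis-linked --------------------------------------
    n_ag = min(40, config.n_fc_features - 2)
    n_sec = min(20, config.n_fc_features - n_ag - 1)
    add_numeric_cluster(0, 0, "AGFC", n_ag, profile["ag_fc"], GROUP_FC, False)
    add_numeric_cluster(0, 1, "SECFC", n_sec, profile["sec_fc"], GROUP_FC, False)
    for i, nm in enumerate(["CATS_total", "CATS_N", "CATS_P", "CATS_E"]):
        features.append((0, NUMERICAL, 2))
        names.append(nm)
        specs.append(FeatureSpec(nm, NUMERICAL, group=GROUP_QUESTIONNAIRE,
                                 depression_related=True))
    for k, mu in enumerate(profile["cats"]):
        blocks[(0, 2, k)] = Block.gaussian(mu, 1.0)
    for nm in ["BDI", "PHQ9", "HRSD", "STAI"]:
        features.append((0, NUMERICAL, 3))
        names.append(nm)
        specs.append(FeatureSpec(nm, NUMERICAL, group=GROUP_QUESTIONNAIRE,
                                 depression_related=True))
    for k, mu in enumerate(profile["severity"]):
        blocks[(0, 3, k)] = Block.gaussian(mu, 1.0)
    for nm in ["BDI_6w", "PHQ9_6w", "HRSD_6w"]:
        features.append((0, NUMERICAL, 4))
        names.append(nm)
        specs.append(FeatureSpec(nm, NUMERICAL, group=GROUP_QUESTIONNAIRE,
                                 depression_related=True))
    for k, mu in enumerate(profile["outcome"]):
        blocks[(0, 4, k)] = Block.gaussian(mu, 1.0)
    # remission flag: depends on subtype (D1 rarely remits), strength scales with e
    w = 0.4 * min(e / 3.0, 1.0)
    features.append((0, CATEGORICAL, 0))
    names.append("Remission")
    specs.append(FeatureSpec("Remission", CATEGORICAL, levels=("no", "yes"),
                             group=GROUP_QUESTIONNAIRE, depression_related=True))
    for k, p_yes in enumerate([0.5, 0.5, 0.5 - w, 0.5 + w, 0.5 + w]):
        blocks[(0, 0 + 10, k)] = Block.categorical([1 - p_yes, p_yes])
    # reuse feature-cluster id 10 for the categorical cluster of view 0
    features[-1] = (0, CATEGORICAL, 10)

    # ---- view 1: nuisance-demographic ----------------------------------
    n_demo = min(4, config.n_questionnaire_features - 11)
    add_numeric_cluster(1, 0, "demo", n_demo, [1.0, -1.0], GROUP_BIOLOGICAL, False)
    features.append((1, CATEGORICAL, 1))
    names.append("sex")
    specs.append(FeatureSpec("sex", CATEGORICAL, levels=("male", "female"),
                             group=GROUP_BIOLOGICAL))
    blocks[(1, 1, 0)] = Block.categorical([0.8, 0.2])
    blocks[(1, 1, 1)] = Block.categorical([0.2, 0.8])
    for i in range(config.n_integer):
        nm = ["Episode", "RecNum"][i] if i < 2 else f"count_{i + 1}"
        features.append((1, INTEGER, 2))
        names.append(nm)
        specs.append(FeatureSpec(nm, INTEGER, group=GROUP_QUESTIONNAIRE))
    if config.n_integer:
        blocks[(1, 2, 0)] = Block.poisson(1.0)
        blocks[(1, 2, 1)] = Block.poisson(3.0)

    # ---- view 2: structureless noise -----------------------------------
    n_fc_noise = config.n_fc_features - n_ag - n_sec
    add_numeric_cluster(2, 0, "FC", n_fc_noise, [0.0], GROUP_FC, False)
    n_q_noise = config.n_questionnaire_features - 11 - n_demo
    add_numeric_cluster(2, 1, "Q", n_q_noise, [0.0], GROUP_QUESTIONNAIRE, False)
    n_snp = config.n_categorical - 2
    for i in range(n_snp):
        nm = f"SNP{i + 1}"
        features.append((2, CATEGORICAL, 2))
        names.append(nm)
        specs.append(FeatureSpec(nm, CATEGORICAL, levels=("AA", "Aa", "aa"),
                                 group=GROUP_BIOLOGICAL))
    if n_snp:
        # Hardy-Weinberg genotype frequencies at minor-allele frequency 0.3
        blocks[(2, 2, 0)] = Block.categorical([0.49, 0.42, 0.09])

    structure = PlantedStructure(
        n_subjects=n, features=features,
        subject_partitions={0: diag, 1: nuis, 2: noise},
        blocks=blocks, missing_rate=0.0, seed=int(rng.integers(2 ** 31)),
        feature_names=names, specs=specs)
    data, truth = simulate_planted(structure)
    data.subject_ids = subject_ids
    data.labels = labels

    # MCAR missingness on non-FC features only (FC matrices are complete)
    if config.missing_rate > 0:
        non_fc = np.array([s.group != GROUP_FC for s in specs])
        mask = rng.random((n, len(specs))) < config.missing_rate
        data.values[mask & non_fc[None, :]] = np.nan

    cluster_names = ["C1", "C2", "D1", "D2", "D3"]
    subtype = {sid: cluster_names[diag[i]]
               for i, sid in enumerate(subject_ids) if labels[sid] == "depressed"}
    outcome = {}
    for i, sid in enumerate(subject_ids):
        if labels[sid] != "depressed":
            continue
        mu = e if cluster_names[diag[i]] == "D1" else 0.0
        outcome[sid] = float(mu + rng.normal(0.0, config.outcome_noise_sd))
    return StudyFixture(data=data, truth=truth, subtype=subtype,
                        cluster_names=cluster_names, outcome=outcome, config=config)


def simulate_recovery_benchmark(seed: int, n_views: int = 3,
                                n_subjects: int = 134,
                                missing_rate: float = 0.10
                                ) -> tuple[DataMatrix, PlantedTruth]:
    """Planted 2- or 3-view mixed-type benchmark for model-recovery checks.

    134 subjects x 200 features, between-cluster mean gaps of 3 block-sd,
    10% missing completely at random. With ``n_views=3``:

    * view 0: 100 numerical features in two feature clusters over a
      3-cluster subject partition (means 0/3/6 and 6/3/0, so each feature
      cluster separates all three subject clusters);
    * view 1: 40 numerical (means -1.5/+1.5), 14 binary categorical
      (level probabilities 0.85/0.15 swapped) and 2 Poisson count features
      (rates 2 and 8) over an independent 2-cluster partition;
    * view 2: 44 numerical features (means -3/0/3) over an independent
      3-cluster partition.

    With ``n_views=2`` the third view is dropped and its 44 numerical
    features join view 1 as a second feature cluster (means -1.5/+1.5 with
    the opposite sign pattern), keeping 200 features in total. Every view
    carries its own subject structure so that no view can be absorbed into
    another without an identifiable fit penalty; all planted partitions
    are mutually independent.
    """
    if n_views not in (2, 3):
        raise ValueError("n_views must be 2 or 3")
    rng = np.random.default_rng(seed)
    n = n_subjects
    part_a = rng.permutation(n) * 3 // n
    part_b = (rng.permutation(n) < n // 2).astype(int)
    part_c = rng.permutation(n) * 3 // n
    feats: list[tuple[int, str, int]] = []
    blocks: dict[tuple[int, int, int], Block] = {}
    feats += [(0, NUMERICAL, 0)] * 60 + [(0, NUMERICAL, 1)] * 40
    for k, mu in enumerate([0.0, 3.0, 6.0]):
        blocks[(0, 0, k)] = Block.gaussian(mu, 1.0)
    for k, mu in enumerate([6.0, 3.0, 0.0]):
        blocks[(0, 1, k)] = Block.gaussian(mu, 1.0)
    feats += [(1, NUMERICAL, 0)] * 40
    for k, mu in enumerate([-1.5, 1.5]):
        blocks[(1, 0, k)] = Block.gaussian(mu, 1.0)
    feats += [(1, CATEGORICAL, 1)] * 14
    blocks[(1, 1, 0)] = Block.categorical([0.85, 0.15])
    blocks[(1, 1, 1)] = Block.categorical([0.15, 0.85])
    feats += [(1, INTEGER, 2)] * 2
    blocks[(1, 2, 0)] = Block.poisson(2.0)
    blocks[(1, 2, 1)] = Block.poisson(8.0)
    if n_views == 3:
        feats += [(2, NUMERICAL, 0)] * 44
        for k, mu in enumerate([-3.0, 0.0, 3.0]):
            blocks[(2, 0, k)] = Block.gaussian(mu, 1.0)
        partitions = {0: part_a, 1: part_b, 2: part_c}
    else:
        feats += [(1, NUMERICAL, 3)] * 44
        for k, mu in enumerate([1.5, -1.5]):
            blocks[(1, 3, k)] = Block.gaussian(mu, 1.0)
        partitions = {0: part_a, 1: part_b}
    structure = PlantedStructure(
        n_subjects=n, features=feats, subject_partitions=partitions,
        blocks=blocks, missing_rate=missing_rate, seed=int(rng.integers(2 ** 31)))
    return simulate_planted(structure)


def write_ground_truth(fixture_or_truth, out_dir: str | Path,
                       feature_names: Sequence[str] | None = None,
                       subject_ids: Sequence[str] | None = None) -> None:
    """Write ground-truth maps as TSV files (features and per-view subjects)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(fixture_or_truth, StudyFixture):
        truth = fixture_or_truth.truth
        feature_names = fixture_or_truth.data.feature_names
        subject_ids = fixture_or_truth.data.subject_ids
        pd.DataFrame({"subject": list(fixture_or_truth.subtype),
                      "subtype": list(fixture_or_truth.subtype.values()),
                      "outcome": [fixture_or_truth.outcome[s]
                                  for s in fixture_or_truth.subtype]}
                     ).to_csv(out / "truth_subtypes.tsv", sep="\t", index=False)
    else:
        truth = fixture_or_truth
        if feature_names is None or subject_ids is None:
            raise ValueError("feature_names and subject_ids required for a bare truth")
    pd.DataFrame({"feature": list(feature_names),
                  "view": truth.feature_view,
                  "feature_cluster": truth.feature_cluster}
                 ).to_csv(out / "truth_features.tsv", sep="\t", index=False)
    rows = []
    for v, part in sorted(truth.subject_partitions.items()):
        for sid, k in zip(subject_ids, part):
            rows.append((sid, v, int(k)))
    pd.DataFrame(rows, columns=["subject", "view", "cluster"]).to_csv(
        out / "truth_subjects.tsv", sep="\t", index=False)
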