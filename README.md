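# mvcoclust

Nonparametric Bayesian **multi-view co-clustering** of mixed-type study
data, with the downstream statistics needed to turn a fitted solution into
interpretable subject subtypes — built for case-control designs that
combine resting-state functional-connectivity (FC) features, clinical
questionnaires and biological markers in one high-dimensional matrix.

## The problem

High-dimensional clinical datasets usually contain *several* cluster
structures at once: one driven by diagnosis, another by demographics,
others by noise. A single clustering over all features blurs them
together. The model implemented here partitions the data matrix at three
levels **simultaneously**:

* features into **views** (exclusive feature selection per clustering
  solution),
* features into **feature clusters** within a view (bundling correlated
  features),
* subjects into **subject clusters**, separately per view.

Each block (feature cluster × subject cluster in a view) is one
parametric distribution by feature type — Gaussian for numerical,
categorical (Dirichlet) for discrete items, Poisson for counts — with
conjugate priors, and all three partitions carry truncated
Dirichlet-process stick-breaking priors (sticks Beta(1, α₁), Beta(1, α₂),
Beta(1, β); defaults α₁ = α₂ = β = 1, γ₀ = σ₀² = λ₀ = 1/100, μ₀ = 0,
ρ₀ = 1, a₀ = b₀ = 1). The number of views and of clusters is inferred, not
fixed. Inference is coordinate-ascent variational Bayes over many random
restarts, selecting the restart with the best ELBO; missing entries are
handled inside the likelihood, with no imputation. See
[docs/methods.md](docs/methods.md) for the model, the inference schedule
and all conventions.

On top of the fitted solution the package provides view characterization
(first-PC FC scores and their between-view correlations, adjusted Rand
agreement with diagnosis labels, depression-related feature proportions,
average Cohen's d between neighboring block means, ANOVA/χ² feature
screens with Bonferroni correction, a Hamming-distance consensus), a
leave-one-out Gaussian-mixture membership predictor, and the two-step
threshold classifier that maps an FC score and a childhood-trauma (CATS)
score to subtypes D1/D2/D3 and treatment-outcome labels
(D1 → resistant, D2/D3 → responsive).

Real datasets of this kind are ethically restricted, so the package ships
first-class synthetic-data generators with exported ground truth
(`mvcoclust.simulate`): planted block structures, ROI time series with
prescribed correlation, and a full 134-subject study-like fixture.

## Worked example

```python
import numpy as np
from mvcoclust import (simulate_depression_study, StudyFixtureConfig,
                       standardize_features)
from mvcoclust.analysis import first_pc_scores
from mvcoclust.classify import fit_threshold_classifier, classify_many

fx = simulate_depression_study(StudyFixtureConfig(seed=1))
data = fx.data                       # 134 subjects x 2763 features
controls = [s for s in data.subject_ids if data.labels[s] == "control"]
std = standardize_features(data, controls)   # FC features vs control baseline

dep = np.array([data.labels[s] == "depressed" for s in data.subject_ids])
fc_score, _ = first_pc_scores(std.values[:, fx.ag_fc_feature_indices()])
cats = std.values[:, fx.cats_feature_index()].copy()
cats[np.isnan(cats)] = np.nanmean(cats)

y = np.array([fx.subtype[s] for s in data.subject_ids
              if data.labels[s] == "depressed"])
clf = fit_threshold_classifier(fc_score[dep], cats[dep], y)
pred = classify_many(clf, fc_score[dep], cats[dep])
print(f"fc_threshold={clf.fc_threshold:.3f}  cats_threshold={clf.cats_threshold:.3f}")
print(f"subtype accuracy (resubstitution): {np.mean(pred['subtype'].values == y):.3f}")
```

prints

```
fc_threshold=-10.175  cats_threshold=-0.307
subtype accuracy (resubstitution): 0.940
```

The FC threshold separates the low-connectivity subtype D3 from the rest
(the FC score is a first principal component over 40 planted FC features,
hence its scale); the CATS threshold then splits high-trauma D1 from
low-trauma D2 among the remaining depressed subjects. 94% of the 67
depressed subjects land in their planted subtype. Fitting the full
co-clustering model itself goes through `mvcoclust.fit(data, ...)`, which
returns the feature→view map, per-view feature and subject clusters, block
posteriors, and per-restart scores.

## Command-line pipeline

A thin CLI orchestrates the same steps with YAML configs, mandatory seeds
and JSON manifests (identical config + seed ⇒ byte-identical outputs):

```bash
mvcoclust simulate --seed 1 --out data/
mvcoclust fit --seed 1 --data data/ --out solution/ --n-restarts 10
mvcoclust characterize --seed 1 --data data/ --solution solution/ --out reports/
mvcoclust classify --seed 1 --data data/ --solution solution/ --out classifier/
```

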