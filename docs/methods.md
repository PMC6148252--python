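# Methods

## Model

`mvcoclust` fits a nonparametric Bayesian *multi-view co-clustering* model
to a subjects × features matrix of mixed-type data. The generative
structure has three simultaneous partitions:

1. **Views.** Features are partitioned exclusively and exhaustively into
   views. A view is a subset of features that carries its own subject
   clustering; irrelevant features for one clustering solution end up in
   other views instead of distorting it.
2. **Feature clusters.** Within a view, features are partitioned into
   clusters of similar (highly correlated) features. Feature clusters are
   kept per feature *type* — numerical, categorical, integer — because a
   block distribution belongs to a single likelihood family.
3. **Subject clusters.** Within each view, subjects are partitioned into
   clusters. Every subject has exactly one cluster per view.

Each *block* — the cell formed by one feature cluster and one subject
cluster inside a view — is modelled by a single distribution chosen by
feature type, with conjugate priors:

* numerical: Gaussian; precision s ~ Ga(γ₀/2, γ₀σ₀²/2), mean μ | s ~
  N(μ₀, (λ₀ s)⁻¹);
* categorical: level probabilities ~ Dirichlet(ρ₀) over the global level
  alphabet (features with fewer declared levels simply never produce counts
  for the surplus levels);
* integer: Poisson; rate ~ Ga(a₀, b₀).

All three partitions carry truncated Dirichlet-process stick-breaking
priors with sticks Beta(1, α₁) for views, Beta(1, α₂) for feature clusters
(applied per view and feature type) and Beta(1, β) for subject clusters.
The α₁→views, α₂→feature clusters, β→subject clusters mapping is recorded
in every run manifest.

Default hyperparameters are non-informative: α₁ = α₂ = β = 1,
γ₀ = σ₀² = 1/100, μ₀ = 0, λ₀ = 1/100, ρ₀ = 1, a₀ = b₀ = 1. All are
configurable through `Hyperparameters`.

## Inference

Inference is coordinate-ascent variational Bayes (CAVI) over a mean-field
posterior: categorical responsibilities for each feature's (view, feature
cluster) assignment and each subject's per-view cluster assignment, Beta
posteriors for the sticks (truncation level T with the T-th stick
degenerate at 1, i.e. the truncated stick-breaking model of Blei & Jordan),
and conjugate Normal–Gamma / Dirichlet / Gamma posteriors for the blocks.
Missing entries contribute nothing to any block likelihood term; no
imputation happens during fitting.

Each iteration updates, in order: block posteriors, view and
feature-cluster sticks, feature responsibilities, subject sticks, subject
responsibilities, then evaluates the ELBO at the current posterior. Every
update is an exact coordinate maximization, so the ELBO is non-decreasing;
the fitter *raises* if it ever observes a relative decrease beyond 1e-8,
treating it as an inference bug rather than noise. Convergence is declared
at relative ELBO change below 1e-6 (default) or 500 iterations.

Hard assignments are taken by maximum posterior responsibility (ties to
the lowest index), empty components are pruned with contiguous relabeling,
and block posteriors are then recomputed at the hard assignments; reported
per-block parameters are posterior means (for Gaussians: posterior-mean
precision and mean).

### Initialization and restarts

Responsibilities are initialized randomly per restart in one of two
styles. *Soft* starts draw flat-Dirichlet random responsibilities
(normalized Exp(1)), letting symmetry break through the data rather than
a frozen configuration — this is what works on realistically sized
matrices. *Hard* starts draw one-hot assignments, providing the immediate
block asymmetry that very small matrices need to escape the symmetric
fixed point (near-uniform soft starts collapse there). Multi-restart fits
use three soft restarts for every hard one. In both styles the number of
initially occupied views is itself drawn uniformly from 2..V per restart:
under coordinate ascent, view consolidation is effectively
one-directional — an empty component's posterior equals its vague prior
(expected precision 100), which makes it so unattractive that features
essentially never migrate into it — so views can merge during fitting but
rarely split, and restarts have to span coarse and fine initial
configurations to reach both regimes.

### Restart selection

Restarts are selected by the converged **ELBO** (the variational surrogate
of the marginal likelihood). The plug-in log-likelihood of the hardened
solution is computed and logged for every restart, but it is not the
default selection score: plug-in likelihood grows monotonically with
partition refinement and therefore systematically prefers fragmented,
overfit solutions. On planted multi-view data the restart that exactly
recovers the planted structure ranks first by ELBO while fragmented
restarts outrank it by raw likelihood. `fit(select="loglik")` restores
likelihood selection if wanted.

The desk-scale default is 10 restarts (CLI) — enough for small planted
structures; production analyses of high-dimensional data should use
hundreds to thousands.

### Known limitations of the model class

Two near-degeneracies are worth knowing about:

* A **structureless** (single-subject-cluster) view can be absorbed into a
  structured view at almost no ELBO cost, since its features fit any
  partition equally well.
* Two views over **independent** subject partitions with k₁ and k₂
  clusters can merge into one view over the product partition (k₁·k₂
  clusters) at identical likelihood and near-identical assignment cost;
  only block-duplication KL terms and the truncation level disfavor the
  merge.

Both are properties of the model, not of the optimizer. The planted
recovery benchmark shipped with the package (see below) is designed so
that neither degeneracy is available: every view carries its own subject
structure and all pairwise product partitions exceed the subject-cluster
truncation.

## Data model and preprocessing

Functional-connectivity (FC) features are Pearson correlations between
ROI-averaged BOLD time series, one numerical feature per unordered ROI
pair (n(n−1)/2 features for n ROIs), named `<roiA>__<roiB>` in ROI-list
order. The shipped ROI inventory lists 90 regions across 14 intrinsic
connectivity networks; cerebellum-free subsets (e.g. 78 regions) are the
caller's choice. Note that a 78-region set yields 78×77/2 = 3003 pair
features; the frequently quoted figure of 2701 corresponds to 74 regions.
This package always computes n(n−1)/2 literally.

Standardization follows the control-referenced convention: FC features are
centred/scaled by the control group's mean and standard deviation (the
control group defines the baseline), all other numerical features by the
all-subject mean and standard deviation; categorical and integer features
pass through untouched. Statistics ignore missing entries, missing entries
stay missing, and the **population** (ddof = 0) standard deviation is used,
so two reference values {1, 3} map exactly to {−1, +1}.

Ordinal questionnaire items (BDI/HRSD item scores) are treated as
categorical, since per-cluster Gaussians fit small ordinal supports
poorly.

## View characterization

* **First-PC scores**: leading principal component of a view's FC feature
  submatrix (column-centred SVD); missing entries are imputed by the
  fitted block posterior mean first, so every subject gets a score. The
  loading sign is oriented so the majority of loadings are non-negative
  (ties toward a non-negative loading sum).
* **Between-view correlations**: Pearson correlation of the per-subject PC
  score vectors; views with fewer than 2 FC features are marked
  not-applicable.
* **Label agreement**: Hubert–Arabie adjusted Rand index between a view's
  subject clusters and the control/depression labels (0 at chance, 1 for
  identical partitions).
* **Depression-related feature proportion**: flagged features divided by
  the view's non-FC feature count (FC features are never counted as
  depression-related). Because the denominator convention is ambiguous in
  general, the proportion over *all* view features is reported alongside.
* **Average Cohen's d**: per eligible FC feature cluster, the fitted
  Gaussian block means over eligible subject clusters are sorted and
  d = (μ₂−μ₁)/√((σ₁²+σ₂²)/2) is evaluated between neighboring means
  (μ₁ < μ₂, so d ≥ 0), then averaged within the view. Eligibility is
  strict "more than three": ≥ 4 FC features per feature cluster and ≥ 4
  depressed subjects per subject cluster. Block sd is the inverse square
  root of the posterior-mean precision — consistent with the fitted model
  rather than empirical cell sd.
* **Per-feature screens**: one-way ANOVA across subject clusters for
  numerical features; chi-square independence on the cluster × value
  crosstable for categorical/integer features; significance at 0.05 with
  Bonferroni correction within feature type within the view. Constant
  features get p = 1. Screens run on the standardized values as clustered,
  without covariate adjustment.
* **Hamming consensus**: subject × subject distance = fraction of views in
  which the two subjects' clusters differ; average-linkage dendrogram
  exported as Newick-style text. These distances are reported as-is (they
  need not obey the triangle inequality for arbitrary partitions).
* **Sensitivity**: refits under perturbed hyperparameters and reports
  view-partition ARI and feature-count-weighted subject-cluster ARI
  against the baseline solution, one row per grid point.

## Subtype classification

Depressed subjects in the diagnosis-linked view fall into three clusters
named by their profile: D3 has the lowest mean FC score; of the other two,
D1 has the higher mean childhood-trauma (CATS) score.

* **LOOCV Gaussian-mixture prediction**: for each depressed subject, the
  subject is held out, per-cluster Gaussian components (means, full
  covariances, mixing weights) are re-estimated from the remaining
  subjects' *known* memberships (supervised — no EM), and the held-out
  subject is assigned to the maximum-posterior component. Accuracies are
  reported per (typically incremental) predictor set: CATS, +FC score,
  +BDI, +rest. Singular covariances are ridge-jittered (multiples of
  1e-6 × mean variance) with the jitter count logged.
* **Two-step threshold classifier**: FC score below a threshold → D3;
  otherwise CATS below a second threshold → D2; otherwise D1. The outcome
  map is D1 → treatment-resistant, D2/D3 → responsive (driven by the
  after-six-week severity profile). Thresholds are *learned* — midpoints
  between sorted unique scores maximizing D3-vs-rest accuracy, then
  D1-vs-D2 accuracy among non-D3 subjects, ties toward the lower
  threshold — rather than hard-coded, since no printed threshold values
  exist. Subjects with a missing FC score (or missing CATS when FC does
  not settle D3) are explicitly unclassifiable.
* **Cluster profiles**: per cluster and feature, mean, sd and a
  high/moderate/low tag relative to the depressed-sample tercile
  boundaries.

## Synthetic data

The raw study data are ethically restricted, so all testing runs on
synthetic data with exported ground truth. Three generators:

* `simulate_planted` draws cells i.i.d. from explicit per-block
  distributions with a Bernoulli missing mask — the workhorse for unit
  and property tests.
* `simulate_roi_timeseries` draws zero-mean ROI × time series whose
  population correlation matrix is prescribed (eigendecomposition factor
  of the target), for exercising the FC feature computation.
* `simulate_depression_study` emulates the study's shape: 67 controls +
  67 depressed by default, 2701 FC-style features, a reduced questionnaire
  battery (40 numerical items including CATS subscales, severity scores
  and six-week follow-ups), 20 categorical items (sex, remission,
  SNP-like factors at Hardy–Weinberg frequencies) and 2 Poisson count
  features. Three views are planted: a diagnosis-linked view with five
  subject clusters (C1, C2 for controls; D1, D2, D3 for depressed), a
  demographic nuisance view over an independent split, and a
  structureless noise view. The depressed profiles follow the
  D1/D2/D3 pattern: D1 high CATS / high FC / poor outcome; D2 low CATS /
  moderate FC / good outcome; D3 high CATS / low FC / high baseline
  severity / good outcome.

Planted effect sizes are not published anywhere, so the defaults are
chosen for testability, not realism: between-cluster separations of 3
block-sd, post-treatment outcome noise sd of 0.5 (treatment response is
strongly subtype-determined in the planted model), 5% missingness on
non-FC features (FC matrices are complete by construction). What passing
tests show is therefore that the *pipeline* recovers planted structure at
comfortable separations — not that such separations exist in real
resting-state data, where effects are far smaller, missingness is not
completely at random, and feature noise is correlated.

The recovery benchmark (`simulate_recovery_benchmark`) plants three views
over 134 subjects × 200 mixed-type features with 3-sd gaps and 10% MCAR
missingness; its composition is documented in the docstring and chosen so
that view identifiability does not hinge on the near-degeneracies above.

## Problem sizes and numerical choices

Shipped checks run at desk scale: recovery uses 10 data seeds × 20
restarts at truncation (5, 4, 4); the study-fixture chain runs at the full
134 × 2763 fixture (PCA and classifiers are cheap); the exhaustive
likelihood oracle enumerates all hard assignments of a 6 × 4 matrix at
truncation (2, 2, 2) and fits with several hundred restarts (tiny fits
cost milliseconds; the global optimum's basin is narrow at that size). The default truncation for real analyses is
(15, 12, 10), covering view/cluster counts typically reported for data of
this kind.

Numerical details worth keeping fixed: responsibilities are normalized in
log space (`logsumexp`); the Gaussian rate update uses the numerically
stable centered form with a clip at zero for the variance part (exact in
real arithmetic, guards float cancellation on near-constant blocks);
entropies use `xlogy` so hard responsibilities contribute exactly zero;
ties in argmax resolve to the lowest index, making reruns byte-identical
under a fixed seed.
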