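# Methods

## Scope and data model

The package implements an exposome-to-disease analysis with three linked
stages: (i) single-exposure epidemiological regression of liver-histology
outcomes on plasma PFHpA, (ii) feature-level association scans across a
metabolome and a proteome layer, and (iii) an unsupervised latent-cluster
integration (LUCID in parallel) whose inclusion probabilities feed a
follow-up outcome regression. Cohort microdata of the emulated study are
restricted, so the package ships a generator that reproduces the *data
structure* — not the data — together with the ground truth needed to test
parameter recovery.

A cohort is a plain `pandas.DataFrame` with one row per subject
(exposure, below-LOD flag, covariates, histology outcomes); an omics
layer is a subjects × features frame plus per-feature QC metadata
(detection fraction, QC CV, below-LOD fraction).

## Preprocessing

* Concentrations below the detection limit (default LOD 0.03 ng/mL) are
  imputed as LOD/2 *before* the log2 transform, so log2(LOD/2) is well
  defined. Imputation touches only flagged entries.
* Exposure enters every model as log2 concentration; a one-unit increase
  is a doubling.
* Feature filters are layer-specific: metabolome features are dropped
  when detected in < 20% of samples or when the QC coefficient of
  variation exceeds 30% (CV computed on raw pre-log QC intensities);
  proteome features are dropped when more than 50% of observations fall
  below the assay LOD. Thresholds are strict inequalities — a protein
  with exactly 50% below-LOD observations is retained.
* "Scaled to a standard normal distribution" is implemented as
  per-feature z-scoring (sample mean 0, SD 1, n−1 denominator); quantile
  normalization was the alternative reading and was not adopted.
  Zero-variance features cannot be scaled and are dropped with a warning.
* Missing values are handled complete-case per analysis stage, logged
  loudly; no imputation of omics values is attempted.

## Exposure-outcome models

Binary endpoints (MASLD yes/no, fibrosis) use maximum-likelihood
logistic regression; 3+ level endpoints (MASLD progression, ballooning,
steatosis grade, activity score) use multinomial logistic regression
with a declared reference level, both via statsmodels. Covariates (age,
sex, race, parental income, site) enter as reference-coded indicators
with the reference fixed to the most frequent level (alphabetical
tie-break) so designs are deterministic. Confidence intervals are Wald
on the log-odds scale; perfect separation is raised as an explicit
error rather than reported as a spurious estimate.

The dose-response trend test bins subjects into eight exposure quantile
groups (type-7 interpolated cut points; a value equal to a cut point
falls in the lower bin). The trend score is the octile rank 1..8 — the
Armitage-style choice, robust to the exposure's skew — configurable to
the octile median exposure. With heavy ties the binning falls back to
the distinct bins available and warns. The design gives the Wald test on
the rank score power ≈ 0.9 at n = 500 for a slope of 0.127 log-odds per
octile at 50% prevalence; the acceptance suite checks both this power
and the type-I rate under a flat risk profile.

## Association scans

Each feature is regressed on log2 exposure plus covariates by OLS.
Because the design is shared across features, the scan solves the normal
equations once and broadcasts across the feature matrix; classical
(homoscedastic) standard errors match default multiple-linear-regression
reporting, and the tests verify per-feature agreement with statsmodels
OLS to 1e−8. Screening keeps features at nominal p < α (default 0.05),
optionally restricted by effect direction, ordered by ascending p —
deliberately without multiplicity correction, because the scan feeds
pathway-level interpretation rather than feature identification; a
Benjamini–Hochberg column is emitted for transparency. The
knowledge-base pathway-overlap step that reduces scan hits to the final
19-metabolite/6-protein signatures depends on an external curated
platform and is consumed as a configuration input (a feature list), not
recomputed.

## Latent-cluster model

Per layer, subjects carry a latent cluster X ∈ {0..K−1} with a
multinomial-logistic prior in the exposure design E (intercept + log2
exposure by default; covariates can be appended but default off — the
emulated analysis adjusts for covariates only in the follow-up
regression) and Gaussian omics emissions with cluster-specific means μ_k
and diagonal covariance. Key numerical choices:

* **Covariance**: diagonal and shared across clusters by default
  (configurable to cluster-specific diagonal). Shared-diagonal keeps the
  likelihood bounded — a cluster cannot collapse onto a single point —
  and is the parsimonious choice when P approaches n. Full covariance is
  excluded.
* **M-step for β**: damped Newton on the responsibility-weighted
  multinomial-logistic objective, warm-started from the previous β, with
  step halving so the M-step never decreases its objective — together
  with the closed-form Gaussian updates this guarantees monotone ascent
  of the observed-data log-likelihood (asserted to 1e−8 slack in every
  test fixture).
* **Initialization and restarts**: restart 0 splits subjects at
  K-quantiles of the first principal component (deterministic and
  invariant to subject order; the component sign is fixed by its largest
  loading); restart 1 uses k-means; further restarts draw random
  Dirichlet responsibilities. Best final log-likelihood wins. The
  subject-permutation invariance property holds exactly for the
  deterministic PC1 path and is tested with `n_restarts=1`.
* **Convergence**: relative log-likelihood change < 1e−6 or 1000
  iterations; a final E-step synchronizes the reported responsibilities
  with the returned parameters.
* **Degeneracies**: a cluster whose responsibility mass falls below 1e−6
  aborts that restart and triggers a redraw (bounded budget); feature
  variances are floored at 1e−6.
* **BIC**: −2·loglik + p·log n with p = (K−1)(1+dim E) + K·P + (#variance
  parameters); ties break toward smaller K.

"In parallel" multi-layer fitting assumes no correlation across layers
given exposure, so the joint likelihood factorizes and the wrapper
literally runs per-layer fits with a shared exposure design, aligned
subjects and the same random state per layer — which makes the
factorization identity testable to 1e−10 rather than approximate.
Whether any parameters should be shared across layers is a modelling
question the factorization renders moot for the unsupervised variant;
the supervised variant (outcome inside the likelihood) is an explicit
non-goal.

Cluster indices are arbitrary up to permutation. `align_clusters`
pins a convention: by exposure-implied propensity (default), by the
mean of an anchor feature, or by outcome rate. The anchor rule is what
ties fitted clusters to the generator's low/high convention in the
recovery tests and the acceptance script.

## Follow-up regression

One joint logistic model regresses the binary outcome on the
non-reference cluster's IP from each layer simultaneously, plus
covariates — IPs enter as continuous probabilities, not hardened labels
(with 0/1 IPs the model reduces exactly to cluster-membership logistic
regression, which the tests assert). Odds ratios are per 0→1 IP
contrast. "High"/"low" risk labels are assigned post hoc from the sign
of each IP coefficient: they are an interpretation layer, not a model
parameter. The per-layer report also carries the exposure→cluster OR per
doubling read directly from the latent model's β, and the scaled
cluster-mean profile (μ is already in standardized units), ordered by
between-cluster separation. A constant IP column is refused — it is
confounded with the intercept.

Soft IPs attenuate the follow-up coefficient toward the null relative
to the generative cluster effect whenever clusters overlap; at the
default cohort size this attenuation is visible in the proteome profile
OR and is a property of the estimand, not an estimation error.

## Synthetic generator

The generator draws: exposure lognormal with meanlog/sdlog matched to a
mean of 0.13 and SD of 0.12 ng/mL, left-censored at 0.03 ng/mL (values
retained, flags set — imputation is preprocessing's job); age uniform
13–19 y; sex Bernoulli(½); race, income and site categorical with
configurable probabilities (placeholder frequencies — the joint
covariate-exposure distribution of the real cohort is unpublished);
per-layer clusters multinomial-logistic in log2 of the *uncensored*
exposure; Gaussian features with cluster means ∓0.5 in standardized
units (19 metabolites, 6 proteins); and a Bernoulli outcome whose
log-odds add one term per layer cluster. Ordinal histology endpoints
ride on the same linear predictor through a proportional-odds latent
variable with fixed cutpoints. Defaults encode the emulated study's
published effect structure: exposure→cluster ORs 1.05 (metabolome) and
2.73 (proteome) per doubling, cluster→outcome ORs 0.51 and 7.08, outcome
intercept −0.3 targeting ≈ 60% prevalence at n = 131.

What the generator does *not* emulate: assay chemistry (batch effects,
plate effects, heteroscedastic intensity noise), feature correlation
within a layer beyond what cluster structure induces, covariate-exposure
confounding, and missingness. Passing tests therefore demonstrate that
the estimators recover the model they assume at realistic sizes — not
robustness to those real-data complications.

## Problem sizes in the test suite

Recovery and calibration checks use the sizes at which their guarantees
are stated: n = 500, P = 5, two clusters at 3-within-SD per-feature mean
separation and unit exposure slope across 100 seeds for recovery;
n = 400 over a {1..4} cluster grid, 50 replicates per scenario, for BIC
consistency; 1000 null features at n = 200 for scan calibration; 500
(type I) and 200 (power) replicates at n = 500 for the trend test; 100
replicates at n = 1000 for follow-up CI coverage; n ≤ 8 instances for
the EM-versus-grid-search oracle. The grid oracle fixes unit variance
and zero prior intercept — a strict subset of EM's parameter space — so
EM's converged log-likelihood must weakly dominate it.

## Known limitations

* Unsupervised variant only; the supervised LUCID extension (outcome in
  the likelihood) and early-integration (concatenated) LUCID are out of
  scope, as are cross-layer correlation modelling and missing-data EM.
* The trend test targets binary endpoints.
* OLS scan uses classical SEs; no heteroscedasticity-robust option.
* The follow-up model is binary-outcome logistic; multinomial follow-up
  is not provided.
* EM finds local optima; the restart schedule makes the tested fixtures
  reliable but pathological likelihood surfaces can still defeat it.
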