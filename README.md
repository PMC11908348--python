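# lucidomics

Latent-cluster multi-omics integration for exposome epidemiology: a
reusable pipeline linking a chemical exposure (plasma PFHpA, a short-chain
PFAS) to a histology-defined liver outcome (MASLD) through metabolome and
proteome signatures, in the setting of an adolescent bariatric-surgery
cohort.

The pipeline covers:

* **Exposure preprocessing** — half-LOD imputation of concentrations below
  the 0.03 ng/mL detection limit, log2 transformation (effects are per
  doubling of exposure), layer-specific omics QC filters (metabolome:
  detection ≥ 20% of samples and QC CV ≤ 30%; proteome: ≤ 50% of
  observations below LOD) and per-feature z-scoring.
* **Exposure-outcome regression** — logistic / multinomial models of each
  histology endpoint on log2 exposure, adjusted for age, sex, race,
  parental income and study site, plus an octile dose-response trend test.
* **Omics-wide association scans (MWAS/PWAS)** — per-feature adjusted OLS
  on log2 exposure with nominal-p screening and direction splitting.
* **The LUCID latent-cluster model** (the core) — unsupervised "latent
  unknown clustering with integrated data", fitted *in parallel*: one
  latent cluster variable per omics layer, estimated by EM, with BIC
  selection of the cluster number.
* **Follow-up inference** — a joint logistic regression of the outcome on
  each layer's inclusion probabilities (IPs), yielding per-profile odds
  ratios and scaled cluster-mean risk signatures.
* **A synthetic cohort generator** that emulates the study's data
  structure (right-skewed censored exposure, exposure-driven latent
  clusters, Gaussian omics layers, cluster-driven outcome) with full
  ground truth for recovery testing. Real cohort data are restricted, so
  every analysis here runs against this generator.

## The model

For subject *i* with exposure design `E_i = (1, log2 PFHpA_i)` and
standardized omics vector `Z_i` (one per layer), the unsupervised LUCID
model for a layer with K latent clusters is

```
P(X_i = k | E_i)  =  softmax_k(β_k · E_i)        (β_0 = 0, reference)
Z_i | X_i = k     ~  N(μ_k, Σ)                   (Σ diagonal, shared)
```

EM maximizes the observed-data log-likelihood
`Σ_i log Σ_k P(X_i=k|E_i; β) · N(Z_i; μ_k, Σ)`; the E-step
responsibilities at convergence are the subject-level inclusion
probabilities `IP_ik`. With several layers and no cross-layer
correlation, the likelihood factorizes, so the parallel fit equals
independent per-layer fits sharing `E`. K is chosen by
`BIC = −2·loglik + p·log n`. The follow-up model is

```
logit P(Y_i = 1) = α + θ_m · IP_i,metabolome + θ_p · IP_i,proteome + covariates
```

with `exp(θ)` the odds of disease for the 0→1 IP contrast.

## Worked example

```python
import numpy as np
import lucidomics as lo

cohort, layers, truth = lo.generate_cohort(seed=1)   # 131 subjects
cohort = lo.prepare_cohort(cohort)                   # ½-LOD + log2
E = cohort["log2_pfhpa"].to_numpy()

est = lo.fit_outcome_model(cohort, lo.OutcomeModelSpec(outcome="masld"))[0]
print(f"MASLD OR per doubling: {est.or_:.2f} ({est.ci_low:.2f}-{est.ci_high:.2f})")

fits = {}
for name, layer in layers.items():
    Z = lo.standardize_features(layer).values
    k, _ = lo.select_k_bic(Z, E, k_grid=(1, 2, 3, 4), random_state=1)
    m = lo.LucidLayer(n_clusters=k, random_state=1).fit(Z, E)
    fits[name] = lo.align_clusters(m, "anchor", anchor=0)

report = lo.risk_profile_report(fits, cohort,
                                covariates=["age", "sex", "race", "income", "site"])
print(report.to_frame()[["layer", "ip_or", "p", "exposure_cluster_or"]])
```

prints (seed 1):

```
MASLD OR per doubling: 1.96 (1.14-3.38)
        layer     ip_or         p  exposure_cluster_or
0  metabolome  0.555272  0.135383             0.873224
1    proteome  3.039440  0.009178             2.793727
```

Reading: each doubling of plasma PFHpA roughly doubles the odds of MASLD
in this synthetic cohort; BIC picks two clusters per layer; membership in
the high proteome cluster triples the odds of disease (p ≈ 0.009) while
the high metabolome cluster is protective (OR ≈ 0.56), and the exposure
is strongly associated with the proteome risk cluster (OR ≈ 2.8 per
doubling) but barely with the metabolome cluster — the qualitative
structure the generator encodes.

A shell interface mirrors the stages (`lucidomics simulate`,
`preprocess`, `outcome-models`, `trend-test`, `omewas`, `lucid-fit`,
`lucid-select-k`, `lucid-followup`); see `lucidomics --help`.

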