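"""Synthetic cohort generator emulating an adolescent bariatric-surgery
exposome study.

The generator produces the data structure the downstream analysis assumes:

* a right-skewed (lognormal) plasma PFHpA exposure, left-censored at an
  assay detection limit of 0.03 ng/mL, with lognormal parameters matched to
  the published summary (mean 0.13, SD 0.12 ng/mL);
* demographic covariates (age, sex, race, parental income, study site);
* one latent cluster variable per omics layer, drawn multinomial-logistic
  in log2 exposure (and optionally covariates) with per-layer log-odds
  ``beta_true``;
* Gaussian omics features with cluster-specific means ``mu_true`` and
  feature SDs ``sigma_true`` (standardized units);
* a binary liver-disease outcome whose log-odds add one term per layer
  cluster (``gamma_outcome``), plus proportional-odds ordinal histology
  endpoints riding on the same linear predictor.

Defaults mirror the integration-analysis conditions: 131 subjects, a
19-feature metabolome and a 6-feature proteome with two clusters each,
exposure-to-cluster odds ratios 1.05 (metabolome) and 2.73 (proteome) per
doubling, and cluster-to-outcome odds ratios 0.51 and 7.08, with the
outcome intercept set for roughly 60% disease prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    BALLOONING_LEVELS,
    FIBROSIS_LEVELS,
    MASLD3_LEVELS,
    NAS_LEVELS,
    STEATOSIS_LEVELS,
    OmicsLayer,
    SimTruth,
)

__all__ = ["SimConfig", "censor_at_lod", "generate_cohort"]

# lognormal(meanlog, sdlog) matched to mean 0.13 / SD 0.12 ng/mL:
#   sdlog^2 = ln(1 + (0.12/0.13)^2), meanlog = ln(0.13) - sdlog^2/2
_DEFAULT_SDLOG = math.sqrt(math.log(1.0 + (0.12 / 0.13) ** 2))
_DEFAULT_MEANLOG = math.log(0.13) - _DEFAULT_SDLOG**2 / 2.0


def _default_beta() -> dict[str, np.ndarray]:
    # columns: [intercept, log2 exposure]; intercept centers cluster
    # prevalence near 1/2 at the mean log2 exposure (~ -3.39)
    mean_log2 = _DEFAULT_MEANLOG / math.log(2.0)
    bm = math.log(1.05)
    bp = math.log(2.73)
    return {
        "metabolome": np.array([[-bm * mean_log2, bm]]),
        "proteome": np.array([[-bp * mean_log2, bp]]),
    }


def _default_mu() -> dict[str, np.ndarray]:
    return {
        "metabolome": np.vstack([np.full(19, -0.5), np.full(19, 0.5)]),
        "proteome": np.vstack([np.full(6, -0.5), np.full(6, 0.5)]),
    }


def _default_sigma() -> dict[str, np.ndarray]:
    return {"metabolome": np.ones(19), "proteome": np.ones(6)}


def _default_gamma() -> dict[str, np.ndarray]:
    return {
        "metabolome": np.array([0.0, math.log(0.51)]),
        "proteome": np.array([0.0, math.log(7.08)]),
    }


def _default_covariates() -> dict:
    return {
        "age": ("uniform", 13.0, 19.0),
        "sex": ("categorical", {"female": 0.5, "male": 0.5}),
        "race": ("categorical", {"white": 0.72, "black": 0.18, "other": 0.10}),
        "income": (
            "categorical",
            {"<25k": 0.3, "25-50k": 0.3, "50-100k": 0.25, ">100k": 0.15},
        ),
        "site": ("categorical", {f"site{i}": 0.2 for i in range(1, 6)}),
    }


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_subjects: int = 131
    exposure_meanlog: float = _DEFAULT_MEANLOG
    exposure_sdlog: float = _DEFAULT_SDLOG
    lod: float = 0.03
    n_clusters: Mapping[str, int] = field(
        default_factory=lambda: {"metabolome": 2, "proteome": 2}
    )
    beta_true: Mapping[str, np.ndarray] = field(default_factory=_default_beta)
    mu_true: Mapping[str, np.ndarray] = field(default_factory=_default_mu)
    sigma_true: Mapping[str, np.ndarray] = field(default_factory=_default_sigma)
    gamma_outcome: Mapping[str, np.ndarray] = field(default_factory=_default_gamma)
    outcome_intercept: float = -0.3
    #: cluster design includes these cohort columns after the exposure
    cluster_covariates: tuple[str, ...] = ()
    covariate_spec: Mapping[str, tuple] = field(default_factory=_default_covariates)
    # proportional-odds cutpoints on the shared latent severity scale
    masld3_cutpoints: tuple[float, ...] = (0.0, 1.6)
    ballooning_cutpoints: tuple[float, ...] = (1.0, 2.5)
    steatosis_cutpoints: tuple[float, ...] = (0.0, 1.8)
    fibrosis_cutpoints: tuple[float, ...] = (1.2,)
    nas_cutpoints: tuple[float, ...] = (0.0, 0.9, 1.8)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.lod <= 0:
            raise ValueError("lod must be positive")
        for layer, k in self.n_clusters.items():
            if k < 1:
                raise ValueError(f"layer {layer!r}: K must be >= 1")
            mu = np.asarray(self.mu_true[layer], float)
            sigma = np.asarray(self.sigma_true[layer], float)
            if mu.shape[0] != k:
                raise ValueError(
                    f"layer {layer!r}: mu_true has {mu.shape[0]} rows, expected K={k}"
                )
            if sigma.shape[0] != mu.shape[1]:
                raise ValueError(f"layer {layer!r}: sigma_true length != n features")
            if np.any(sigma <= 0):
                raise ValueError(f"layer {layer!r}: sigma_true must be positive")
            beta = np.asarray(self.beta_true[layer], float)
            if k > 1 and beta.shape[0] != k - 1:
                raise ValueError(
                    f"layer {layer!r}: beta_true has {beta.shape[0]} rows, expected K-1={k - 1}"
                )
            gamma = np.asarray(self.gamma_outcome[layer], float)
            if gamma.shape[0] != k:
                raise ValueError(f"layer {layer!r}: gamma_outcome length != K")


def censor_at_lod(values: np.ndarray, lod: float) -> tuple[np.ndarray, np.ndarray]:
    """Flag concentrations below the detection limit.

    Values are returned unchanged; imputation is a separate, later step so
    the censoring status stays available downstream.
    """
    if lod <= 0:
        raise ValueError("lod must be positive")
    values = np.asarray(values, float)
    return values.copy(), values < lod


def _draw_covariates(rng: np.random.Generator, n: int, spec: Mapping[str, tuple]) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name, rule in spec.items():
        kind = rule[0]
        if kind == "uniform":
            cols[name] = rng.uniform(rule[1], rule[2], n)
        elif kind == "categorical":
            levels = list(rule[1].keys())
            probs = np.array(list(rule[1].values()), float)
            probs = probs / probs.sum()
            cols[name] = rng.choice(levels, size=n, p=probs)
        else:
            raise ValueError(f"unknown covariate rule {kind!r} for {name!r}")
    return pd.DataFrame(cols)


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _ordinal_from_latent(latent: np.ndarray, cutpoints: tuple[float, ...], levels: list[str]) -> np.ndarray:
    idx = np.searchsorted(np.asarray(cutpoints, float), latent, side="left")
    return np.asarray(levels, object)[idx]


def generate_cohort(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, dict[str, OmicsLayer], SimTruth]:
    """Draw one synthetic cohort.

    Returns the cohort table (raw exposure + below-LOD flags, covariates,
    outcomes), the omics layers keyed by name, and the ground truth needed
    by recovery tests. The same config and seed give bit-identical output.
    """
    config = config or SimConfig()
    if seed is not None:
        config = _replace_seed(config, seed)
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    exposure = rng.lognormal(config.exposure_meanlog, config.exposure_sdlog, n)
    values, below = censor_at_lod(exposure, config.lod)
    log2_e = np.log2(exposure)  # truth drives the clusters, pre-censoring

    cov = _draw_covariates(rng, n, config.covariate_spec)

    # cluster design: intercept + log2 exposure (+ optional covariates)
    design_cols = [np.ones(n), log2_e]
    for c in config.cluster_covariates:
        design_cols.append(pd.to_numeric(cov[c]).to_numpy(float))
    E = np.column_stack(design_cols)

    labels: dict[str, np.ndarray] = {}
    layers: dict[str, OmicsLayer] = {}
    subject_ids = [f"S{i:04d}" for i in range(n)]
    for layer, k in config.n_clusters.items():
        beta = np.asarray(config.beta_true[layer], float)
        mu = np.asarray(config.mu_true[layer], float)
        sigma = np.asarray(config.sigma_true[layer], float)
        if k == 1:
            lab = np.zeros(n, dtype=int)
        else:
            if beta.shape[1] != E.shape[1]:
                raise ValueError(
                    f"layer {layer!r}: beta_true has {beta.shape[1]} columns, "
                    f"cluster design has {E.shape[1]}"
                )
            logits = np.hstack([np.zeros((n, 1)), E @ beta.T])
            probs = _softmax_rows(logits)
            u = rng.random(n)
            lab = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        labels[layer] = lab
        P = mu.shape[1]
        Z = mu[lab] + rng.standard_normal((n, P)) * sigma
        values_df = pd.DataFrame(
            Z,
            index=pd.Index(subject_ids, name="subject_id"),
            columns=[f"{layer[:4]}_{j:03d}" for j in range(P)],
        )
        layers[layer] = OmicsLayer(
            name=layer,
            values=values_df,
            detection=pd.Series(1.0, index=values_df.columns),
            qc_cv=pd.Series(0.05, index=values_df.columns),
            below_lod_frac=pd.Series(0.0, index=values_df.columns),
        )

    # outcome: one additive cluster term per layer on the log-odds scale
    linpred = np.full(n, config.outcome_intercept)
    for layer in config.n_clusters:
        gamma = np.asarray(config.gamma_outcome[layer], float)
        linpred = linpred + gamma[labels[layer]]
    masld = (rng.random(n) < 1.0 / (1.0 + np.exp(-linpred))).astype(int)

    # ordinal histology endpoints: proportional odds on the same predictor
    def latent() -> np.ndarray:
        return linpred + rng.logistic(0.0, 1.0, n)

    cohort = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "pfhpa_ngml": values,
            "pfhpa_below_lod": below,
            **{c: cov[c].to_numpy() for c in cov.columns},
            "masld": masld,
            "masld3": _ordinal_from_latent(latent(), config.masld3_cutpoints, MASLD3_LEVELS),
            "ballooning": _ordinal_from_latent(
                latent(), config.ballooning_cutpoints, BALLOONING_LEVELS
            ),
            "steatosis": _ordinal_from_latent(
                latent(), config.steatosis_cutpoints, STEATOSIS_LEVELS
            ),
            "fibrosis": _ordinal_from_latent(
                latent(), config.fibrosis_cutpoints, FIBROSIS_LEVELS
            ),
            "nas": _ordinal_from_latent(latent(), config.nas_cutpoints, NAS_LEVELS),
        }
    )

    truth = SimTruth(
        cluster_labels=labels,
        exposure_uncensored=exposure,
        beta_true={k: np.asarray(v, float) for k, v in config.beta_true.items()},
        mu_true={k: np.asarray(v, float) for k, v in config.mu_true.items()},
        sigma_true={k: np.asarray(v, float) for k, v in config.sigma_true.items()},
        gamma_outcome={k: np.asarray(v, float) for k, v in config.gamma_outcome.items()},
        outcome_intercept=config.outcome_intercept,
        seed=config.seed,
    )
    return cohort, layers, truth


def _replace_seed(config: SimConfig, seed: int) -> SimConfig:
    import dataclasses

    return dataclasses.replace(config, seed=seed)
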