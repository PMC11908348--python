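"""Follow-up inference on fitted latent-cluster models.

A single joint logistic regression of the binary liver-disease outcome on
the per-layer inclusion probabilities (the non-reference cluster's IP from
each layer, entered as continuous probabilities) with covariate
adjustment; odds ratios are for the 0-to-1 IP contrast. Risk labels
("low"/"high") are an interpretation layer assigned post hoc from the sign
of each IP coefficient. The per-layer risk profile also carries the
exposure-to-cluster odds ratio per doubling (from the latent model's beta)
and the scaled cluster-mean feature signature.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from ._design import build_design, check_full_rank
from .datatypes import LayerRisk, RiskProfileReport, SignatureList
from .exposure_outcome import _fit_logit
from .lucid import LucidLayer

logger = logging.getLogger(__name__)

__all__ = ["ip_outcome_regression", "profile_summary", "risk_profile_report"]


def _ip_vector(ip, layer: str) -> np.ndarray:
    """Non-reference-cluster inclusion probability as a 1-D vector."""
    if isinstance(ip, LucidLayer):
        ip = ip.responsibilities_
    ip = np.asarray(ip, float)
    if ip.ndim == 2:
        if ip.shape[1] == 1:
            raise ValueError(f"layer {layer!r} has a single cluster; no IP contrast")
        if ip.shape[1] > 2:
            logger.warning(
                "layer %s has %d clusters; using cluster 1 IP vs reference 0",
                layer, ip.shape[1],
            )
        ip = ip[:, 1]
    return ip


def ip_outcome_regression(
    fits: Mapping[str, "LucidLayer | np.ndarray"],
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    outcome: str = "masld",
):
    """Joint logistic fit: outcome ~ IP_layer1 + IP_layer2 + covariates.

    ``fits`` maps layer name to a fitted :class:`LucidLayer` or directly
    to an IP matrix/vector (rows aligned to the cohort). Returns the
    statsmodels result plus the IP column names, via a small record used
    by :func:`risk_profile_report`.
    """
    covariates = list(covariates) if covariates is not None else []
    y = cohort[outcome].to_numpy(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")

    data = cohort.copy()
    ip_cols = []
    for layer, fit in fits.items():
        v = _ip_vector(fit, layer)
        if len(v) != len(cohort):
            raise ValueError(f"layer {layer!r} IPs not aligned to cohort rows")
        if np.ptp(v) < 1e-12:
            raise ValueError(
                f"layer {layer!r} IP column is constant: confounded with the "
                "intercept, no identifiable IP effect"
            )
        col = f"ip_{layer}"
        data[col] = v
        ip_cols.append(col)

    X = build_design(data, ip_cols + covariates, exposure_col=None)
    check_full_rank(X)
    res = _fit_logit(y, X)
    return res, X, ip_cols


def risk_profile_report(
    fits: Mapping[str, LucidLayer],
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    outcome: str = "masld",
    exposure_design=None,
) -> RiskProfileReport:
    """Full follow-up report: per-layer IP odds ratios for the outcome,
    exposure-to-cluster odds ratios per doubling, scaled cluster-mean
    profiles, and high/low risk labels."""
    res, X, ip_cols = ip_outcome_regression(fits, cohort, covariates, outcome)
    z975 = scipy.stats.norm.ppf(0.975)
    layers: dict[str, LayerRisk] = {}
    for layer, fit in fits.items():
        j = list(X.columns).index(f"ip_{layer}")
        b, se = float(res.params[j]), float(res.bse[j])
        if not isinstance(fit, LucidLayer):
            raise TypeError("risk_profile_report requires fitted LucidLayer models")
        # exposure slope: beta_[0] is cluster 1 vs 0; column 1 is log2 exposure
        exp_or = float(np.exp(fit.beta_[0, 1])) if fit.beta_.size else float("nan")
        high = 1 if b > 0 else 0
        K = fit.mu_.shape[0]
        risk_labels = ["low"] * K
        risk_labels[high] = "high"
        profile = profile_summary(fit, risk_labels=risk_labels)
        layers[layer] = LayerRisk(
            layer=layer,
            ip_or=float(np.exp(b)),
            ip_ci_low=float(np.exp(b - z975 * se)),
            ip_ci_high=float(np.exp(b + z975 * se)),
            ip_p=float(res.pvalues[j]),
            exposure_cluster_or=exp_or,
            high_risk_cluster=high,
            cluster_risk_labels=risk_labels,
            profile=profile,
        )
    return RiskProfileReport(
        layers=layers,
        n=len(cohort),
        outcome=outcome,
        covariates=list(covariates) if covariates else [],
        loglik=float(res.llf),
    )


def profile_summary(
    fit: LucidLayer,
    signature: SignatureList | list[str] | None = None,
    risk_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster scaled feature means, ordered by the between-cluster
    separation |mu_high - mu_low| descending (feature-name tie-break).

    Features are standardized before fitting, so ``mu_`` is already in
    scaled units and is reported as-is.
    """
    names = fit.feature_names_ or [f"f{j}" for j in range(fit.mu_.shape[1])]
    if signature is not None:
        feats = signature.features if isinstance(signature, SignatureList) else list(signature)
        if len(feats) == 0:
            raise ValueError("empty signature")
        missing = [f for f in feats if f not in names]
        if missing:
            raise KeyError(f"signature features absent from fit: {missing}")
    else:
        feats = names
    idx = [names.index(f) for f in feats]
    K = fit.mu_.shape[0]
    cols = {f"cluster_{k}": fit.mu_[k, idx] for k in range(K)}
    out = pd.DataFrame(cols, index=pd.Index(feats, name="feature"))
    sep = (out.max(axis=1) - out.min(axis=1)).to_numpy()
    order = np.lexsort((np.asarray(feats, object), -sep))
    out = out.iloc[order]
    if risk_labels is not None:
        out.columns = [f"cluster_{k} ({risk_labels[k]})" for k in range(K)]
    return out
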