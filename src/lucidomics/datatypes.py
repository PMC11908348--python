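"""Shared container types for cohort, omics-layer, and result objects.

The cohort itself is a plain :class:`pandas.DataFrame` with a documented
column convention (see :data:`COHORT_COLUMNS`); the light dataclasses here
carry the pieces that need metadata a bare frame cannot hold (per-feature
QC numbers, selection provenance, simulation ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Column convention for the per-subject cohort table.
COHORT_COLUMNS = {
    "subject_id": "unique subject key",
    "pfhpa_ngml": "plasma PFHpA concentration, ng/mL (raw; below-LOD values retained)",
    "pfhpa_below_lod": "bool, True where the raw value fell below the detection limit",
    "log2_pfhpa": "log2-transformed exposure after half-LOD imputation (added by preprocessing)",
    "age": "years",
    "sex": "categorical",
    "race": "categorical",
    "income": "parental income bracket, categorical",
    "site": "study site, categorical",
    "masld": "binary liver-disease outcome (0/1)",
    "masld3": "three-level histology: No MASLD / MASLD not MASH / MASH",
    "ballooning": "hepatocellular ballooning: none / few / many",
    "steatosis": "steatosis grade: none / 5-33% / 34-67%",
    "fibrosis": "fibrosis: none / present",
    "nas": "activity score category: none / 1 / 2 / >=3",
}

MASLD3_LEVELS = ["No MASLD", "MASLD not MASH", "MASH"]
BALLOONING_LEVELS = ["none", "few", "many"]
STEATOSIS_LEVELS = ["none", "5-33%", "34-67%"]
FIBROSIS_LEVELS = ["none", "present"]
NAS_LEVELS = ["none", "1", "2", ">=3"]


@dataclass
class OmicsLayer:
    """A subjects x features matrix plus the per-feature QC metadata the
    filtering rules need.

    ``values`` rows are indexed by subject_id and columns by feature name.
    Metabolome intensities are log2 scale; proteome values are NPX (already
    log2). ``detection`` is the fraction of samples in which a feature was
    detected; ``qc_cv`` the coefficient of variation in QC samples;
    ``below_lod_frac`` the fraction of observations below the assay LOD.
    Any metadata series may be None when the corresponding rule is unused.
    """

    name: str
    values: pd.DataFrame
    detection: pd.Series | None = None
    qc_cv: pd.Series | None = None
    below_lod_frac: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names in layer {self.name!r}: {dup}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, features: Sequence[str]) -> "OmicsLayer":
        """Return a copy restricted to ``features`` (order preserved)."""
        missing = [f for f in features if f not in self.values.columns]
        if missing:
            raise KeyError(f"features absent from layer {self.name!r}: {missing}")
        meta = {}
        for attr in ("detection", "qc_cv", "below_lod_frac"):
            s = getattr(self, attr)
            meta[attr] = s.loc[list(features)] if s is not None else None
        return OmicsLayer(self.name, self.values[list(features)].copy(), **meta)


@dataclass
class SignatureList:
    """Feature subset carried forward into the latent-cluster model."""

    layer: str
    features: list[str]
    rule: str = ""

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in signature list")


@dataclass
class EffectEstimate:
    """A single exposure-effect estimate: odds ratio per doubling with
    Wald 95% CI."""

    outcome: str
    contrast: str
    or_: float
    ci_low: float
    ci_high: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_ <= self.ci_high):
            raise ValueError("confidence interval does not bracket the OR")


def estimates_to_frame(estimates: Sequence[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "outcome": e.outcome,
                "contrast": e.contrast,
                "or": e.or_,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p": e.p,
                "n": e.n,
            }
            for e in estimates
        ]
    )


@dataclass
class SimTruth:
    """Ground truth retained by the synthetic generator for recovery tests."""

    cluster_labels: dict[str, np.ndarray]
    exposure_uncensored: np.ndarray
    beta_true: dict[str, np.ndarray]
    mu_true: dict[str, np.ndarray]
    sigma_true: dict[str, np.ndarray]
    gamma_outcome: dict[str, np.ndarray]
    outcome_intercept: float
    seed: int


@dataclass
class LayerRisk:
    """Follow-up summary for one omics layer."""

    layer: str
    ip_or: float
    ip_ci_low: float
    ip_ci_high: float
    ip_p: float
    exposure_cluster_or: float
    high_risk_cluster: int
    cluster_risk_labels: list[str]
    profile: pd.DataFrame  # features x clusters, scaled means


@dataclass
class RiskProfileReport:
    """Joint IP-to-outcome regression output across layers."""

    layers: dict[str, LayerRisk]
    n: int
    outcome: str
    covariates: list[str] = field(default_factory=list)
    loglik: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, lr in self.layers.items():
            rows.append(
                {
                    "layer": name,
                    "ip_or": lr.ip_or,
                    "ci_low": lr.ip_ci_low,
                    "ci_high": lr.ip_ci_high,
                    "p": lr.ip_p,
                    "exposure_cluster_or": lr.exposure_cluster_or,
                    "high_risk_cluster": lr.high_risk_cluster,
                }
            )
        return pd.DataFrame(rows)
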