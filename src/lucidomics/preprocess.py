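"""Exposure and omics preprocessing.

Pipeline order: below-LOD concentrations are imputed as half the detection
limit first, so the subsequent log2 transform is well defined; omics
features then pass layer-specific QC filters (metabolome: detected in at
least 20% of samples and QC coefficient of variation at most 30%;
proteome: at most 50% of observations below the assay LOD) before
per-feature z-scoring (mean 0, SD 1, n-1 denominator).

The transformers follow the scikit-learn ``fit``/``transform`` protocol so
they compose into pipelines; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import OmicsLayer

logger = logging.getLogger(__name__)

__all__ = [
    "impute_half_lod",
    "log2_exposure",
    "filter_features",
    "standardize_features",
    "prepare_cohort",
    "HalfLODImputer",
    "OmicsFeatureFilter",
    "OmicsStandardizer",
]

#: layer-specific QC rules: (metadata attribute, comparison, threshold)
LAYER_RULES: dict[str, list[tuple[str, str, float]]] = {
    "metabolome": [
        ("detection", "lt", 0.20),  # drop if detected in < 20% of samples
        ("qc_cv", "gt", 0.30),  # drop if QC CV > 30%
    ],
    "proteome": [
        ("below_lod_frac", "gt", 0.50),  # drop if > 50% of obs below LOD
    ],
}

_RULE_LABEL = {
    ("detection", "lt"): "detection < {thr:.0%} of samples",
    ("qc_cv", "gt"): "QC CV > {thr:.0%}",
    ("below_lod_frac", "gt"): "> {thr:.0%} of observations below LOD",
}


def impute_half_lod(
    values: np.ndarray, flags: np.ndarray, lod: float
) -> np.ndarray:
    """Replace below-LOD concentrations by half the detection limit."""
    if lod <= 0:
        raise ValueError("lod must be positive")
    values = np.asarray(values, float)
    flags = np.asarray(flags, bool)
    if values.shape != flags.shape:
        raise ValueError(
            f"values and flags length mismatch: {values.shape} vs {flags.shape}"
        )
    out = values.copy()
    out[flags] = lod / 2.0
    return out


def log2_exposure(values: np.ndarray) -> np.ndarray:
    """Base-2 log of concentrations: a one-unit increase is a doubling."""
    values = np.asarray(values, float)
    if np.any(values <= 0):
        raise ValueError("log2 transform requires strictly positive values")
    return np.log2(values)


def prepare_cohort(cohort: pd.DataFrame, lod: float = 0.03) -> pd.DataFrame:
    """Impute the exposure at half LOD and add the ``log2_pfhpa`` column."""
    out = cohort.copy()
    flags = out["pfhpa_below_lod"].to_numpy(bool) if "pfhpa_below_lod" in out else (
        out["pfhpa_ngml"].to_numpy(float) < lod
    )
    imputed = impute_half_lod(out["pfhpa_ngml"].to_numpy(float), flags, lod)
    out["pfhpa_ngml"] = imputed
    out["pfhpa_below_lod"] = flags
    out["log2_pfhpa"] = log2_exposure(imputed)
    return out


@dataclass
class FilterReport:
    """Which features each QC rule removed."""

    layer: str
    dropped: pd.DataFrame  # columns: feature, rule
    n_in: int
    n_out: int

    def to_dict(self) -> dict:
        return {
            "layer": self.layer,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "dropped": self.dropped.to_dict(orient="records"),
        }


class OmicsFeatureFilter(BaseEstimator, TransformerMixin):
    """Drop features failing the QC rules of their layer.

    Parameters
    ----------
    rules : mapping or None
        ``{metadata_attr: (op, threshold)}`` triples; when None the layer's
        standard rule set (see :data:`LAYER_RULES`) is looked up by
        ``layer.name`` at fit time.
    """

    def __init__(self, rules: list[tuple[str, str, float]] | None = None):
        self.rules = rules

    def fit(self, layer: OmicsLayer, y=None):
        rules = self.rules
        if rules is None:
            if layer.name not in LAYER_RULES:
                raise ValueError(
                    f"no standard rule set for layer {layer.name!r}; "
                    f"known layers: {sorted(LAYER_RULES)}"
                )
            rules = LAYER_RULES[layer.name]
        dropped: dict[str, str] = {}
        for attr, op, thr in rules:
            meta = getattr(layer, attr, None)
            if meta is None:
                raise ValueError(
                    f"layer {layer.name!r} lacks {attr!r} metadata required "
                    "by its filter rules"
                )
            meta = meta.reindex(layer.values.columns)
            if meta.isna().any():
                missing = meta.index[meta.isna()].tolist()
                raise ValueError(f"missing {attr!r} metadata for {missing}")
            bad = meta < thr if op == "lt" else meta > thr
            label = _RULE_LABEL.get((attr, op), f"{attr} {op} {thr}").format(thr=thr)
            for f in meta.index[bad]:
                dropped.setdefault(f, label)  # first triggering rule wins
        self.rules_ = rules
        self.dropped_ = pd.DataFrame(
            sorted(dropped.items()), columns=["feature", "rule"]
        )
        self.keep_ = [f for f in layer.values.columns if f not in dropped]
        return self

    def transform(self, layer: OmicsLayer) -> OmicsLayer:
        return layer.subset(self.keep_)

    def report(self, layer: OmicsLayer) -> FilterReport:
        return FilterReport(
            layer=layer.name,
            dropped=self.dropped_,
            n_in=layer.values.shape[1],
            n_out=len(self.keep_),
        )


def filter_features(
    layer: OmicsLayer, rules: list[tuple[str, str, float]] | None = None
) -> tuple[OmicsLayer, FilterReport]:
    f = OmicsFeatureFilter(rules=rules).fit(layer)
    return f.transform(layer), f.report(layer)


class OmicsStandardizer(BaseEstimator, TransformerMixin):
    """Per-feature z-scoring (sample mean 0, sample SD 1, n-1 denominator).

    Zero-variance features cannot be scaled; they are reported and dropped
    (``dropped_constant_``).
    """

    def fit(self, layer: OmicsLayer, y=None):
        if layer.n_subjects < 2:
            raise ValueError("standardization requires at least 2 subjects")
        X = layer.values
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        const = sd.index[sd == 0.0].tolist()
        if const:
            logger.warning(
                "dropping %d zero-variance feature(s) in layer %s: %s",
                len(const), layer.name, const,
            )
        self.mean_ = mean.drop(const)
        self.scale_ = sd.drop(const)
        self.dropped_constant_ = const
        return self

    def transform(self, layer: OmicsLayer) -> OmicsLayer:
        out = layer.subset(list(self.mean_.index))
        out.values = (out.values - self.mean_) / self.scale_
        return out


def standardize_features(layer: OmicsLayer) -> OmicsLayer:
    s = OmicsStandardizer().fit(layer)
    return s.transform(layer)


class HalfLODImputer(BaseEstimator, TransformerMixin):
    """Stateless half-LOD imputation as a pipeline step over (values, flags)."""

    def __init__(self, lod: float = 0.03):
        self.lod = lod

    def fit(self, X, y=None):
        if self.lod <= 0:
            raise ValueError("lod must be positive")
        return self

    def transform(self, X):
        values, flags = X
        return impute_half_lod(values, flags, self.lod)
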