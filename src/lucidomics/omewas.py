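"""Metabolome-/proteome-wide association scans (MWAS / PWAS).

For every feature in a layer, an ordinary least-squares regression of the
feature value on log2-transformed exposure plus covariates; the exposure
coefficient, its classical SE and two-sided p-value make up the per-feature
association result. Because the design matrix is shared across features,
the scan solves the normal equations once and broadcasts over the feature
matrix, which keeps a 20k-feature metabolome scan in milliseconds.

Screening retains features at a nominal alpha (no multiplicity correction
for selection, by design — the scan feeds pathway-level analysis, not
feature identification); a Benjamini-Hochberg column is emitted for
transparency.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._design import build_design, check_full_rank
from .datatypes import OmicsLayer, SignatureList

logger = logging.getLogger(__name__)

__all__ = ["OmicsWideAssociation", "run_omewas", "screen_features"]


class OmicsWideAssociation(BaseEstimator):
    """Per-feature adjusted linear regression on log2 exposure.

    After ``fit(layer, cohort)``, ``results_`` holds one row per feature:
    ``feature, layer, beta, se, t, p, p_bh, direction`` sorted by the
    layer's feature order. Zero-variance features are skipped and listed
    in ``skipped_``.
    """

    def __init__(
        self,
        covariates: list[str] | None = None,
        exposure_col: str = "log2_pfhpa",
    ):
        self.covariates = covariates
        self.exposure_col = exposure_col

    def fit(self, layer: OmicsLayer, cohort: pd.DataFrame):
        covariates = list(self.covariates) if self.covariates is not None else []
        values = layer.values
        cohort = cohort.set_index("subject_id") if "subject_id" in cohort.columns else cohort
        if not values.index.equals(cohort.index):
            if set(values.index) != set(cohort.index):
                raise ValueError("subjects differ between layer and cohort")
            cohort = cohort.loc[values.index]

        X = build_design(cohort, covariates, exposure_col=self.exposure_col)
        n, d = X.shape
        if n <= d:
            raise ValueError(f"underdetermined scan: n={n} subjects, {d} parameters")
        check_full_rank(X)

        sd = values.std(axis=0, ddof=1)
        skipped = sd.index[sd == 0.0].tolist()
        if skipped:
            logger.warning("skipping %d zero-variance feature(s): %s", len(skipped), skipped)
        feats = [f for f in values.columns if f not in skipped]
        Y = values[feats].to_numpy(float)

        A = X.to_numpy(float)
        XtX = A.T @ A
        B = np.linalg.solve(XtX, A.T @ Y)  # (d, P)
        resid = Y - A @ B
        dof = n - d
        s2 = (resid**2).sum(axis=0) / dof
        j = list(X.columns).index(self.exposure_col)
        var_j = np.linalg.inv(XtX)[j, j]
        beta = B[j]
        se = np.sqrt(s2 * var_j)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p = 2.0 * scipy.stats.t.sf(np.abs(t), dof)
        p_bh = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

        self.results_ = pd.DataFrame(
            {
                "feature": feats,
                "layer": layer.name,
                "beta": beta,
                "se": se,
                "t": t,
                "p": p,
                "p_bh": p_bh,
                "direction": np.where(beta > 0, "up", "down"),
            }
        )
        self.skipped_ = skipped
        self.dof_ = dof
        return self


def run_omewas(
    layer: OmicsLayer,
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    exposure_col: str = "log2_pfhpa",
) -> pd.DataFrame:
    """Functional wrapper: the per-feature association table."""
    return OmicsWideAssociation(
        covariates=covariates, exposure_col=exposure_col
    ).fit(layer, cohort).results_


def screen_features(
    results: pd.DataFrame,
    alpha: float = 0.05,
    direction: str | None = None,
) -> SignatureList:
    """Retain features with p < alpha (and, optionally, a required effect
    direction), ordered by ascending p with feature-name tie-break."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if direction not in (None, "up", "down"):
        raise ValueError(f"direction must be 'up', 'down' or None, not {direction!r}")
    if len(results) == 0:
        return SignatureList(layer="", features=[], rule=f"p < {alpha}")
    hits = results[results["p"] < alpha]
    rule = f"nominal p < {alpha}"
    if direction is not None:
        hits = hits[hits["direction"] == direction]
        rule += f", direction = {direction}"
    hits = hits.sort_values(["p", "feature"], kind="stable")
    layer = results["layer"].iloc[0] if "layer" in results else ""
    return SignatureList(layer=str(layer), features=hits["feature"].tolist(), rule=rule)
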