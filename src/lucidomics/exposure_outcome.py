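"""Exposure-to-histology regression models.

Each model regresses a liver-histology outcome on log2-transformed plasma
PFHpA (so coefficients are per doubling of exposure), adjusted for age,
sex, race, parental income and study site. Binary outcomes use logistic
regression; multi-level outcomes use multinomial logistic regression with
a stated reference category. A dose-response trend test bins subjects into
exposure octiles and tests the Wald p-value of a single per-octile rank
score in the adjusted logistic model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from ._design import build_design, check_full_rank
from .datatypes import EffectEstimate, estimates_to_frame

logger = logging.getLogger(__name__)

__all__ = [
    "OutcomeModelSpec",
    "ExposureOutcomeModel",
    "fit_outcome_model",
    "octile_trend_test",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ["age", "sex", "race", "income", "site"]


@dataclass
class OutcomeModelSpec:
    """What to regress and how."""

    outcome: str
    family: str = "logistic"  # logistic | multinomial
    reference: str | None = None
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))

    def __post_init__(self) -> None:
        if self.family not in ("logistic", "multinomial"):
            raise ValueError(f"unknown family {self.family!r}")


class ExposureOutcomeModel(BaseEstimator):
    """Adjusted exposure-outcome regression, per doubling of exposure.

    Parameters mirror :class:`OutcomeModelSpec`; after ``fit`` the
    estimates are in ``estimates_`` (list of :class:`EffectEstimate`, one
    per non-reference outcome level) and ``results_`` (DataFrame).
    """

    def __init__(
        self,
        outcome: str = "masld",
        family: str = "logistic",
        reference: str | None = None,
        covariates: list[str] | None = None,
        exposure_col: str = "log2_pfhpa",
    ):
        self.outcome = outcome
        self.family = family
        self.reference = reference
        self.covariates = covariates
        self.exposure_col = exposure_col

    def fit(self, cohort: pd.DataFrame, y=None):
        spec = OutcomeModelSpec(
            outcome=self.outcome,
            family=self.family,
            reference=self.reference,
            covariates=(
                list(self.covariates) if self.covariates is not None else list(DEFAULT_COVARIATES)
            ),
        )
        self.estimates_ = _fit(cohort, spec, self.exposure_col)
        self.results_ = estimates_to_frame(self.estimates_)
        return self


def fit_outcome_model(
    cohort: pd.DataFrame, spec: OutcomeModelSpec, exposure_col: str = "log2_pfhpa"
) -> list[EffectEstimate]:
    """One :class:`EffectEstimate` per non-reference outcome level."""
    return _fit(cohort, spec, exposure_col)


def _fit(cohort: pd.DataFrame, spec: OutcomeModelSpec, exposure_col: str) -> list[EffectEstimate]:
    data = cohort.dropna(subset=[spec.outcome, exposure_col] + spec.covariates)
    if len(data) < len(cohort):
        logger.warning(
            "complete-case analysis: dropped %d of %d subjects with missing values",
            len(cohort) - len(data), len(cohort),
        )
    y_raw = data[spec.outcome]
    levels = _outcome_levels(y_raw, spec)
    X = build_design(data, spec.covariates, exposure_col=exposure_col)
    check_full_rank(X)
    if len(data) <= X.shape[1]:
        raise ValueError(
            f"n={len(data)} does not exceed the {X.shape[1]} model parameters"
        )
    n = len(data)
    j = list(X.columns).index(exposure_col)
    z975 = scipy.stats.norm.ppf(0.975)

    if spec.family == "logistic" or len(levels) == 2:
        ref = levels[0]
        alt = levels[1]
        y = (y_raw.astype(str) == str(alt)).astype(float) if len(levels) == 2 else y_raw
        res = _fit_logit(y.to_numpy(float), X)
        b, se = res.params[j], res.bse[j]
        return [
            EffectEstimate(
                outcome=spec.outcome,
                contrast=f"{alt} vs {ref}",
                or_=float(np.exp(b)),
                ci_low=float(np.exp(b - z975 * se)),
                ci_high=float(np.exp(b + z975 * se)),
                p=float(res.pvalues[j]),
                n=n,
            )
        ]

    # multinomial: reference must map to code 0
    cat = pd.Categorical(y_raw.astype(str), categories=[str(l) for l in levels])
    codes = np.asarray(cat.codes)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.MNLogit(codes, X.to_numpy(float)).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as e:
            raise ValueError(f"perfect separation in {spec.outcome!r} model") from e
    out = []
    for m, alt in enumerate(levels[1:]):
        # statsmodels MNLogit params are (k_exog, K-1)
        b = float(res.params[j, m])
        se = float(res.bse[j, m])
        out.append(
            EffectEstimate(
                outcome=spec.outcome,
                contrast=f"{alt} vs {levels[0]}",
                or_=float(np.exp(b)),
                ci_low=float(np.exp(b - z975 * se)),
                ci_high=float(np.exp(b + z975 * se)),
                p=float(res.pvalues[j, m]),
                n=n,
            )
        )
    return out


def _outcome_levels(y: pd.Series, spec: OutcomeModelSpec) -> list[str]:
    observed = y.astype(str).value_counts()
    if (observed == 0).any() or observed.size < 2:
        raise ValueError(
            f"outcome {spec.outcome!r} needs >= 2 observed levels, got {observed.size}"
        )
    if isinstance(y.dtype, pd.CategoricalDtype):
        declared = [str(l) for l in y.cat.categories]
        empty = [l for l in declared if l not in observed.index]
        if empty:
            raise ValueError(f"empty outcome level(s) in {spec.outcome!r}: {empty}")
        levels = declared
    else:
        levels = sorted(observed.index)
    ref = str(spec.reference) if spec.reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference {ref!r} is not a level of {spec.outcome!r}")
    return [ref] + [l for l in levels if l != ref]


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            return sm.Logit(y, X.to_numpy(float)).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as e:
            raise ValueError("perfect separation in logistic model") from e


def octile_trend_test(
    cohort: pd.DataFrame,
    outcome: str = "masld",
    covariates: list[str] | None = None,
    n_bins: int = 8,
    score: str = "rank",
    exposure_col: str = "log2_pfhpa",
) -> tuple[pd.Series, float]:
    """Dose-response trend across exposure octiles.

    Subjects are binned at type-7 exposure quantile cut points (ties fall
    in the lower bin); a single continuous score per bin — its rank 1..8
    by default, or the bin median exposure with ``score='median'`` —
    replaces the exposure in the adjusted logistic model, and the trend
    p-value is the Wald p of that score.

    Returns (bin assignment per subject, p_trend).
    """
    if covariates is None:
        covariates = list(DEFAULT_COVARIATES)
    x = cohort[exposure_col].to_numpy(float)
    if len(np.unique(x)) < n_bins:
        raise ValueError(
            f"need >= {n_bins} distinct exposure values, got {len(np.unique(x))}"
        )
    y = cohort[outcome].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome!r} is constant")

    bins, k = _quantile_bins(x, n_bins)
    if k < n_bins:
        warnings.warn(
            f"heavy ties: only {k} non-empty exposure bins formed instead of {n_bins}",
            stacklevel=2,
        )
    if score == "rank":
        s = bins + 1.0
    elif score == "median":
        med = np.array([np.median(x[bins == b]) for b in range(k)])
        s = med[bins]
    else:
        raise ValueError(f"unknown score {score!r}")

    data = cohort.copy()
    data["_trend_score"] = s
    X = build_design(data, covariates, exposure_col="_trend_score")
    check_full_rank(X)
    res = _fit_logit(y, X)
    j = list(X.columns).index("_trend_score")
    p_trend = float(res.pvalues[j])
    return pd.Series(bins + 1, index=cohort.index, name="octile"), p_trend


def _quantile_bins(x: np.ndarray, n_bins: int) -> tuple[np.ndarray, int]:
    """Type-7 quantile cut points; ties at a cut point go to the lower bin."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])  # interior cuts
    cuts = np.unique(qs)
    bins = np.searchsorted(cuts, x, side="left")
    # relabel to consecutive 0..k-1 in case some bins came out empty
    used = np.unique(bins)
    remap = {b: i for i, b in enumerate(used)}
    bins = np.array([remap[b] for b in bins])
    return bins, len(used)
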