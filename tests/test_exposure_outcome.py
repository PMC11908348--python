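"""Exposure-outcome regressions: closed-form checks, null calibration,
model-family equivalences, and the octile trend machinery."""

import numpy as np
import pandas as pd
import pytest

import lucidomics as lo
from lucidomics.exposure_outcome import _quantile_bins, octile_trend_test


def _toy_2x2():
    """30 cases/10 controls among exposed vs 10 cases/30 controls:
    OR = (30*30)/(10*10) = 9."""
    rows = (
        [(1, 1)] * 30 + [(1, 0)] * 10 + [(0, 1)] * 10 + [(0, 0)] * 30
    )
    df = pd.DataFrame(rows, columns=["exposed", "case"])
    df["subject_id"] = [f"s{i}" for i in range(len(df))]
    return df


class TestFitOutcomeModel:
    def test_2x2_closed_form_odds_ratio(self):
        spec = lo.OutcomeModelSpec(outcome="case", family="logistic", covariates=[])
        est = lo.fit_outcome_model(_toy_2x2(), spec, exposure_col="exposed")
        assert len(est) == 1
        assert est[0].or_ == pytest.approx(9.0, rel=1e-4)

    def test_null_cohort_ci_covers_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "subject_id": range(2000),
                "log2_pfhpa": rng.normal(size=2000),
                "masld": rng.integers(0, 2, 2000),
            }
        )
        spec = lo.OutcomeModelSpec(outcome="masld", covariates=[])
        est = lo.fit_outcome_model(df, spec)
        assert est[0].ci_low < 1.0 < est[0].ci_high

    def test_multinomial_two_levels_equals_logistic(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "subject_id": range(400),
                "log2_pfhpa": rng.normal(size=400),
            }
        )
        df["y"] = (
            rng.random(400) < 1 / (1 + np.exp(-0.5 * df["log2_pfhpa"]))
        ).map({True: "case", False: "ctrl"})
        logit = lo.fit_outcome_model(
            df, lo.OutcomeModelSpec(outcome="y", family="logistic", reference="ctrl", covariates=[])
        )[0]
        mnl = lo.fit_outcome_model(
            df, lo.OutcomeModelSpec(outcome="y", family="multinomial", reference="ctrl", covariates=[])
        )[0]
        assert np.log(mnl.or_) == pytest.approx(np.log(logit.or_), abs=1e-5)

    def test_multinomial_three_levels_contrasts(self, default_cohort):
        cohort, _, _ = default_cohort
        spec = lo.OutcomeModelSpec(
            outcome="masld3", family="multinomial", reference="No MASLD",
            covariates=["age", "sex"],
        )
        est = lo.fit_outcome_model(cohort, spec)
        contrasts = {e.contrast for e in est}
        assert contrasts == {"MASLD not MASH vs No MASLD", "MASH vs No MASLD"}
        for e in est:
            assert e.ci_low <= e.or_ <= e.ci_high

    def test_or_invariant_to_exposure_rescaling(self):
        """Rescaling raw concentrations shifts log2 exposure by a constant,
        which the intercept absorbs: the per-doubling OR is unchanged."""
        df = _toy_cohort(seed=5, n=500)
        spec = lo.OutcomeModelSpec(outcome="masld", covariates=[])
        or1 = lo.fit_outcome_model(df, spec)[0].or_
        df2 = df.copy()
        df2["log2_pfhpa"] = df2["log2_pfhpa"] + np.log2(7.3)  # x7.3 rescale
        or2 = lo.fit_outcome_model(df2, spec)[0].or_
        assert or1 == pytest.approx(or2, rel=1e-8)

    def test_empty_outcome_level_raises(self):
        df = _toy_cohort(seed=6, n=100)
        df["y"] = pd.Categorical(
            np.where(df["masld"] == 1, "a", "b"), categories=["a", "b", "c"]
        )
        with pytest.raises(ValueError, match="empty|levels"):
            lo.fit_outcome_model(
                df, lo.OutcomeModelSpec(outcome="y", family="multinomial", covariates=[])
            )

    def test_estimator_wrapper(self, default_cohort):
        cohort, _, _ = default_cohort
        m = lo.ExposureOutcomeModel(outcome="masld").fit(cohort)
        assert list(m.results_.columns) == [
            "outcome", "contrast", "or", "ci_low", "ci_high", "p", "n",
        ]
        assert m.results_.loc[0, "n"] == len(cohort)


def _toy_cohort(seed: int, n: int, slope: float = 0.0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(slope * x)))
    return pd.DataFrame(
        {
            "subject_id": range(n),
            "log2_pfhpa": x,
            "masld": (rng.random(n) < p).astype(int),
        }
    )


class TestOctileTrend:
    def test_bins_partition_and_balance(self):
        rng = np.random.default_rng(2)
        df = _toy_cohort(seed=2, n=800)
        bins, p = octile_trend_test(df, covariates=[])
        assert len(bins) == 800
        sizes = bins.value_counts()
        assert sorted(sizes.index) == list(range(1, 9))
        assert sizes.max() - sizes.min() <= 1

    def test_ties_fall_back_with_warning(self):
        df = _toy_cohort(seed=3, n=200)
        # 8 distinct values but 96% of the mass on one of them
        df["log2_pfhpa"] = np.concatenate([np.zeros(193), np.arange(1.0, 8.0)])
        with pytest.warns(UserWarning, match="non-empty"):
            bins, _ = octile_trend_test(df, covariates=[])
        assert bins.nunique() < 8

    def test_constant_outcome_raises(self):
        df = _toy_cohort(seed=4, n=100)
        df["masld"] = 1
        with pytest.raises(ValueError, match="constant"):
            octile_trend_test(df, covariates=[])

    def test_too_few_distinct_exposures_raises(self):
        df = _toy_cohort(seed=5, n=100)
        df["log2_pfhpa"] = np.repeat([1.0, 2.0], 50)
        with pytest.raises(ValueError, match="distinct"):
            octile_trend_test(df, covariates=[])

    def test_median_score_variant(self):
        df = _toy_cohort(seed=6, n=400, slope=0.8)
        _, p_rank = octile_trend_test(df, covariates=[], score="rank")
        _, p_med = octile_trend_test(df, covariates=[], score="median")
        assert p_rank < 0.05 and p_med < 0.05

    def test_quantile_ties_to_lower_bin(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
        bins, k = _quantile_bins(x, 2)
        # the type-7 median of x is 2.0; the tied value goes to the lower bin
        assert bins[x == 2.0][0] == 0
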