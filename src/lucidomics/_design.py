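"""Deterministic design-matrix construction shared by the regression stages.

Categorical covariates enter as reference-coded indicator columns with the
reference fixed to the most frequent level (ties broken alphabetically) so
the same cohort always yields the same design, regardless of row order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _is_categorical(s: pd.Series) -> bool:
    return (
        isinstance(s.dtype, pd.CategoricalDtype)
        or s.dtype == object
        or pd.api.types.is_bool_dtype(s)
        or pd.api.types.is_string_dtype(s)
    )


def reference_level(s: pd.Series) -> str:
    """Most frequent level; alphabetical tie-break."""
    counts = s.astype(str).value_counts()
    top = counts[counts == counts.max()].index
    return sorted(top)[0]


def encode_covariates(cohort: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Reference-coded covariate columns (no intercept).

    Numeric covariates pass through; categorical ones expand into indicator
    columns named ``<col>[<level>]`` for every non-reference level, ordered
    alphabetically.
    """
    blocks: list[pd.DataFrame] = []
    for col in covariates:
        if col not in cohort.columns:
            raise KeyError(f"covariate {col!r} not in cohort table")
        s = cohort[col]
        if _is_categorical(s):
            s = s.astype(str)
            ref = reference_level(s)
            levels = sorted(lv for lv in s.unique() if lv != ref)
            block = pd.DataFrame(
                {f"{col}[{lv}]": (s == lv).astype(float) for lv in levels},
                index=cohort.index,
            )
        else:
            block = s.astype(float).to_frame(col)
        blocks.append(block)
    if not blocks:
        return pd.DataFrame(index=cohort.index)
    return pd.concat(blocks, axis=1)


def build_design(
    cohort: pd.DataFrame,
    covariates: list[str],
    exposure_col: str | None = "log2_pfhpa",
    intercept: bool = True,
) -> pd.DataFrame:
    """Full regression design: intercept, exposure, then covariate blocks."""
    parts: list[pd.DataFrame] = []
    if intercept:
        parts.append(pd.DataFrame({"const": np.ones(len(cohort))}, index=cohort.index))
    if exposure_col is not None:
        if exposure_col not in cohort.columns:
            raise KeyError(
                f"exposure column {exposure_col!r} not in cohort table; "
                "run preprocessing first"
            )
        parts.append(cohort[[exposure_col]].astype(float))
    parts.append(encode_covariates(cohort, covariates))
    X = pd.concat(parts, axis=1)
    if not np.isfinite(X.to_numpy()).all():
        bad = X.columns[~np.isfinite(X.to_numpy()).all(axis=0)].tolist()
        raise ValueError(f"non-finite values in design columns {bad}")
    return X


def check_full_rank(X: pd.DataFrame) -> None:
    """Raise with the offending columns when the design is rank deficient."""
    A = X.to_numpy(float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # pivoted QR flags the dependent columns deterministically
        _, r, piv = _qr_pivoted(A)
        keep = piv[: rank]
        drop = sorted(set(range(A.shape[1])) - set(keep.tolist()))
        names = [X.columns[j] for j in drop]
        raise ValueError(f"design matrix is rank deficient; offending columns: {names}")


def _qr_pivoted(A: np.ndarray):
    import scipy.linalg

    q, r, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    return q, r, piv
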