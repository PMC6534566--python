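"""Behavioral matrix preparation: covariate residualization, then rank-based
inverse-normal (quantile) normalization."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata


def residualize(y_raw: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Per-measure OLS residuals against an intercept plus covariates.

    Parameters
    ----------
    y_raw
        (subjects, measures) array.
    covariates
        (subjects, p) numeric design (categoricals already encoded).
    """
    y_raw = np.asarray(y_raw, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if y_raw.ndim == 1:
        y_raw = y_raw[:, None]
    n = y_raw.shape[0]
    if covariates.shape[0] != n:
        raise ValueError("subject count mismatch between Y and covariates")
    design = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate design is rank deficient")
    beta, *_ = np.linalg.lstsq(design, y_raw, rcond=None)
    return y_raw - design @ beta


def quantile_normalize(column: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform of one measure.

    Ties receive average ranks; rank r (1-based) maps to
    Phi^{-1}((r - 0.5) / n). The output depends on the input only
    through its ranks, so any strictly monotone transform of the input
    yields the identical output.
    """
    column = np.asarray(column, dtype=float)
    n = column.size
    if n < 3 or np.all(column == column[0]):
        raise ValueError("need at least 3 non-identical values")
    ranks = rankdata(column, method="average")
    return ndtri((ranks - 0.5) / n)


def encode_covariates(covariates: pd.DataFrame) -> np.ndarray:
    """Numeric design from a covariate table.

    Numeric columns pass through; string/categorical columns (gender,
    race, ...) are one-hot encoded with the first level dropped.
    """
    num = covariates.select_dtypes(include=[np.number])
    cat = covariates.select_dtypes(exclude=[np.number])
    parts = []
    if not num.empty:
        parts.append(num.to_numpy(dtype=float))
    if not cat.empty:
        parts.append(pd.get_dummies(cat, drop_first=True).to_numpy(dtype=float))
    if not parts:
        raise ValueError("no covariates provided")
    return np.column_stack(parts)


def prepare_behavior(
    behavior: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Residualize every measure on the covariates, then quantile normalize.

    The order follows the standard preparation for variance-component
    analysis: nuisance regression first, then the rank-based
    inverse-normal transform of each residual column. Subjects (rows)
    must be aligned between the two tables.
    """
    if behavior.isna().any().any():
        raise ValueError("behavior table has missing entries")
    if len(behavior) != len(covariates):
        raise ValueError("behavior and covariates have different subject counts")
    design = encode_covariates(covariates)
    resid = residualize(behavior.to_numpy(dtype=float), design)
    normed = np.column_stack([quantile_normalize(resid[:, j]) for j in range(resid.shape[1])])
    return pd.DataFrame(normed, index=behavior.index, columns=behavior.columns)
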