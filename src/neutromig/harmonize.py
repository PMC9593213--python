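"""Feature selection, covariate correction, normalization.

The harmonization pipeline runs in a fixed order on the experiments x
features matrix (and analogously on cytokine panels):

1. ``select_features`` — greedy correlation pruning: while any feature
   pair has |Pearson r| above the threshold (default 0.85), drop from the
   worst-offending pair the member with the higher mean absolute
   correlation to all other remaining features.
2. ``residualize`` — per feature, an ordinary least squares fit on the
   covariate design (gender, age, season, batch; categoricals as indicator
   contrasts) and replacement of the feature by its residual.
3. ``zscore`` — per feature, (x - mean) / sd pooled over all experiments
   of all chemokine arms, so a positive value means "above the cohort
   mean for this feature".

Cytokine tables are natural-log transformed first and corrected for age,
gender and measurement date (days since the earliest measurement, linear).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("neutromig.harmonize")

__all__ = [
    "select_features",
    "residualize",
    "zscore",
    "preprocess_cytokines",
    "build_design_matrix",
    "harmonize_profiles",
]

#: Standard-deviation convention: population SD (ddof=0) throughout.
_DDOF = 0


def select_features(matrix: pd.DataFrame, r_threshold: float = 0.85,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop one member of every feature pair correlated above the threshold.

    Iteratively finds the remaining pair with the largest |Pearson r|
    exceeding ``r_threshold`` and removes the member with the higher mean
    absolute correlation to all other remaining features. Ties (both in
    the offending pair and in the removal choice) are broken by column
    order: the earlier column is kept. Constant columns have undefined
    correlations and are dropped up front with a warning.

    Returns the reduced matrix and a removal log with one row per dropped
    feature (feature, reason, partner, r).
    """
    if len(matrix) < 2:
        raise ValueError("feature selection requires at least 2 rows")
    removed: list[dict] = []
    work = matrix.copy()

    constant = [c for c in work.columns if work[c].std(ddof=_DDOF) == 0
                or not np.isfinite(work[c]).all()]
    for c in constant:
        logger.warning("dropping constant/non-finite feature %r", c)
        removed.append({"feature": c, "reason": "constant", "partner": "", "r": np.nan})
    work = work.drop(columns=constant)

    while work.shape[1] >= 2:
        corr = work.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= r_threshold:
            break
        i, j = min(i, j), max(i, j)
        # mean |r| with all other remaining features
        others = [k for k in range(work.shape[1]) if k not in (i, j)]
        mean_i = corr[i, others].mean() if others else corr[i, j]
        mean_j = corr[j, others].mean() if others else corr[i, j]
        drop_idx = j if mean_j >= mean_i else i  # tie -> drop the later column
        keep_idx = i if drop_idx == j else j
        removed.append({
            "feature": work.columns[drop_idx],
            "reason": "correlated",
            "partner": work.columns[keep_idx],
            "r": float(work.corr().iloc[i, j]),
        })
        work = work.drop(columns=[work.columns[drop_idx]])

    log = pd.DataFrame(removed, columns=["feature", "reason", "partner", "r"])
    return work, log


def build_design_matrix(covariates: pd.DataFrame,
                        categorical: Sequence[str] = ("gender", "season", "batch"),
                        ) -> pd.DataFrame:
    """Intercept + numeric covariates + indicator contrasts for categoricals.

    Each categorical covariate is expanded to k-1 indicator columns
    (first level as reference); numeric covariates enter linearly.
    """
    cols = {"intercept": np.ones(len(covariates))}
    design = pd.DataFrame(cols, index=covariates.index)
    for name in covariates.columns:
        col = covariates[name]
        if name in categorical or col.dtype == object or isinstance(
                col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            design = pd.concat([design, dummies], axis=1)
        else:
            design[name] = pd.to_numeric(col, errors="coerce")
    return design


def residualize(matrix: pd.DataFrame, covariates: pd.DataFrame,
                categorical: Sequence[str] = ("gender", "season", "batch"),
                ) -> pd.DataFrame:
    """Replace every feature by its OLS residual on the covariate design.

    Rows with missing covariates are excluded from the fit and get missing
    corrected values. A rank-deficient design has its aliased columns
    dropped with a warning. Residuals are orthogonal to every retained
    design column, so a second application is a no-op.
    """
    design = build_design_matrix(covariates.loc[matrix.index], categorical)
    complete = design.notna().all(axis=1) & matrix.notna().all(axis=1)
    X = design.loc[complete].to_numpy(dtype=float)

    # detect and drop aliased (linearly dependent) columns via QR pivoting
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        keep: list[int] = []
        for k in range(X.shape[1]):
            trial = X[:, keep + [k]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(k)
        dropped = [design.columns[k] for k in range(X.shape[1]) if k not in keep]
        logger.warning("rank-deficient covariate design; dropping aliased "
                       "columns %s", dropped)
        X = X[:, keep]

    Y = matrix.loc[complete].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = pd.DataFrame(np.nan, index=matrix.index, columns=matrix.columns)
    out.loc[complete] = resid
    return out


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize every column to mean 0, SD 1 (population SD) over all rows.

    Pooled over every experiment of every chemokine arm: a positive value
    is above the cohort-wide mean of that feature. Raises on a zero-SD
    column, naming it.
    """
    if len(matrix) < 2:
        raise ValueError("zscore requires at least 2 rows")
    mean = matrix.mean()
    sd = matrix.std(ddof=_DDOF)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"cannot z-score zero-variance column(s): {list(zero.index)}")
    return (matrix - mean) / sd


def preprocess_cytokines(values: pd.DataFrame, meta: pd.DataFrame,
                         impute_nonpositive: bool = False) -> pd.DataFrame:
    """Log-transform, covariate-correct and normalize a cytokine panel.

    ``values`` holds concentrations (pg/ml, donors x analytes); ``meta``
    must provide ``age``, ``gender`` and ``date`` per donor. Nonpositive
    concentrations cannot be log-transformed: they are flagged and treated
    as missing, or imputed at half the analyte minimum positive value when
    ``impute_nonpositive`` is set. The date enters the linear correction
    as days since the earliest measurement.
    """
    vals = values.copy().astype(float)
    bad = vals <= 0
    if bad.to_numpy().any():
        n_bad = int(bad.to_numpy().sum())
        if impute_nonpositive:
            logger.warning("imputing %d nonpositive concentrations at analyte min/2", n_bad)
            for col in vals.columns[bad.any()]:
                positive_min = vals.loc[vals[col] > 0, col].min()
                vals.loc[bad[col], col] = positive_min / 2.0
        else:
            logger.warning("flagging %d nonpositive concentrations as missing", n_bad)
            vals = vals.mask(bad)

    logged = np.log(vals)
    dates = pd.to_datetime(meta.loc[vals.index, "date"])
    covs = pd.DataFrame({
        "age": pd.to_numeric(meta.loc[vals.index, "age"]),
        "gender": meta.loc[vals.index, "gender"],
        "date_days": (dates - dates.min()).dt.days.astype(float),
    }, index=vals.index)
    corrected = residualize(logged, covs, categorical=("gender",))
    return zscore(corrected)


def harmonize_profiles(matrix: pd.DataFrame, covariates: pd.DataFrame,
                       r_threshold: float = 0.85,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full harmonization: select -> residualize -> zscore.

    Returns the normalized matrix and the feature-removal log.
    """
    selected, log = select_features(matrix, r_threshold=r_threshold)
    corrected = residualize(selected, covariates)
    return zscore(corrected), log
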