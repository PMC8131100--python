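"""Cohort screening and per-subject derived quantities.

Three utilities used before model fitting: a Mahalanobis-distance multivariate
outlier screen (chi-square threshold), trimmed-scores-regression imputation of
missing entries via an internal PCA, and per-subject ordinary-least-squares
slopes of cognitive scores against age.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["mahalanobis_outliers", "tsr_impute", "TSRResult",
           "cognitive_slopes", "DegenerateDataError", "COGNITIVE_SCORES"]

logger = logging.getLogger(__name__)

COGNITIVE_SCORES = ["MMSE", "ADAS11", "ADAS13", "MEM", "EF"]


class DegenerateDataError(ValueError):
    """Covariance not invertible even after regularization."""


def mahalanobis_outliers(data: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of multivariate outliers at significance ``alpha``.

    A subject is an outlier when its squared Mahalanobis distance to the
    sample mean exceeds the upper-``alpha`` chi-square quantile with
    one degree of freedom per feature. A singular covariance is
    ridge-regularized (logged); if still singular the data are degenerate.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be subjects x features")
    n, f = data.shape
    if n <= f:
        raise ValueError(f"need more subjects ({n}) than features ({f})")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    centered = data - data.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * np.trace(cov) / f
        logger.warning("singular covariance; ridge-regularizing with %.3g", ridge)
        try:
            cov_inv = np.linalg.inv(cov + ridge * np.eye(f))
        except np.linalg.LinAlgError:
            raise DegenerateDataError("covariance singular after regularization")
    d2 = np.einsum("ij,jk,ik->i", centered, cov_inv, centered)
    return d2 > stats.chi2.ppf(1.0 - alpha, df=f)


@dataclass
class TSRResult:
    completed: np.ndarray
    converged: bool
    n_iter: int
    observed_error: list[float]  # RMS reconstruction error on observed cells


def tsr_impute(data: np.ndarray, n_components: int | None = None,
               tol: float = 1e-8, max_iter: int = 500,
               explained_variance: float = 0.90) -> TSRResult:
    """Impute missing entries by trimmed scores regression with internal PCA.

    Missing cells (NaN) start at column means. Each iteration fits a
    rank-``n_components`` PCA to the completed, column-centered matrix; for
    every incomplete row the component scores are regressed from the observed
    features only (the "trimmed" scores, via the pseudo-inverse of the
    observed-part loadings) and the missing features are reconstructed from
    those scores. Iteration stops when the imputed values change by less than
    ``tol`` in relative terms. When ``n_components`` is None the smallest rank
    reaching ``explained_variance`` of the variance is used each iteration.
    """
    X = np.array(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be subjects x features")
    miss = np.isnan(X)
    if not miss.any():
        return TSRResult(X, True, 0, [])
    if miss.all(axis=1).any():
        bad = np.where(miss.all(axis=1))[0]
        raise ValueError(f"fully-missing row(s): {bad.tolist()}")
    if miss.all(axis=0).any():
        bad = np.where(miss.all(axis=0))[0]
        raise ValueError(f"fully-missing column(s): {bad.tolist()}")
    n, f = X.shape
    if n_components is not None and not 1 <= n_components < min(n, f):
        raise ValueError("n_components must be in [1, min(subjects, features))")

    col_mean = np.nanmean(X, axis=0)
    X[miss] = np.broadcast_to(col_mean, X.shape)[miss]

    errors: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = X.mean(axis=0)
        Xc = X - mu
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        if n_components is None:
            var = s ** 2
            cum = np.cumsum(var) / var.sum() if var.sum() > 0 else np.ones_like(var)
            r = int(np.searchsorted(cum, explained_variance) + 1)
            r = min(r, min(n, f) - 1)
        else:
            r = n_components
        P = Vt[:r].T  # features x r loadings

        newX = X.copy()
        for i in np.where(miss.any(axis=1))[0]:
            o = ~miss[i]
            scores = np.linalg.pinv(P[o]) @ Xc[i, o]
            newX[i, miss[i]] = P[miss[i]] @ scores + mu[miss[i]]

        recon = (U[:, :r] * s[:r]) @ Vt[:r] + mu
        obs_err = float(np.sqrt(np.mean((recon[~miss] - X[~miss]) ** 2)))
        errors.append(obs_err)

        denom = max(float(np.abs(X[miss]).max()), 1e-12)
        delta = float(np.abs(newX[miss] - X[miss]).max()) / denom
        X = newX
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"tsr_impute: not converged after {max_iter} iterations "
                      f"(best iterate returned)", stacklevel=2)
    return TSRResult(X, converged, it, errors)


def cognitive_slopes(table: pd.DataFrame,
                     scores: list[str] | None = None) -> pd.DataFrame:
    """Per-subject OLS slope of each cognitive score against age.

    ``table`` is long-format with columns subject_id, age, score_name, value.
    Scores with fewer than two non-missing visits get NaN (flagged undefined,
    never zero-filled). Output: subjects x scores DataFrame, points per year.
    """
    required = {"subject_id", "age", "score_name", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cognition table missing columns: {sorted(missing)}")
    scores = scores or sorted(table["score_name"].unique())
    subjects = sorted(table["subject_id"].unique())
    out = pd.DataFrame(np.nan, index=subjects, columns=scores)
    out.index.name = "subject_id"
    for (subj, score), grp in table.groupby(["subject_id", "score_name"]):
        if score not in out.columns:
            continue
        ok = grp["value"].notna() & grp["age"].notna()
        if ok.sum() < 2 or grp.loc[ok, "age"].nunique() < 2:
            continue
        age = grp.loc[ok, "age"].to_numpy(float)
        val = grp.loc[ok, "value"].to_numpy(float)
        out.loc[subj, score] = np.polyfit(age, val, 1)[0]
    return out
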