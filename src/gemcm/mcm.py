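"""Forward model and regression formulation of the multifactorial causal model.

The rate of change of factor m at region i is modelled as

    dS_i^m/dt = sum_n (alpha0[n->m] + sum_k alpha[k, n->m] * G[k, i]) * S_i^n
                + beta[m] * sum_{j != i} C[j, i] * (S_j^m - S_i^m)

where G is the z-scored genes x regions expression template and C the
anatomical connectome. Fitting proceeds by computing annualized
finite-difference derivatives between consecutive visits and regressing them
on a design matrix whose columns are the per-region predictor terms evaluated
at the left endpoint of each interval; the regression coefficients are exactly
the flattened parameter vector (see ``FactorParameterSet.flatten``).
"""

from __future__ import annotations

import numpy as np

from .datatypes import (AlignmentError, Connectome, FactorParameterSet,
                        GeneExpressionTemplate, SimulationUnstableError,
                        SubjectTimeseries)

__all__ = [
    "finite_difference_derivatives",
    "build_design_matrix",
    "simulate_forward",
    "r2_score",
]


def _factor_index(ts: SubjectTimeseries, factor: str | int) -> int:
    if isinstance(factor, (int, np.integer)):
        if not 0 <= int(factor) < ts.n_factors:
            raise ValueError(f"factor index {factor} out of range")
        return int(factor)
    try:
        return ts.factor_names.index(factor)
    except ValueError:
        raise ValueError(f"unknown factor {factor!r}; have {ts.factor_names}") from None


def _check_alignment(ts: SubjectTimeseries, template: GeneExpressionTemplate,
                     conn: Connectome) -> None:
    if list(template.region_ids) != list(ts.region_ids):
        offenders = [r for r in ts.region_ids if r not in template.region_ids]
        raise AlignmentError(
            f"template regions do not align with timeseries regions; "
            f"missing from template: {offenders[:5]}")
    if list(conn.region_ids) != list(ts.region_ids):
        offenders = [r for r in ts.region_ids if r not in conn.region_ids]
        raise AlignmentError(
            f"connectome regions do not align with timeseries regions; "
            f"missing from connectome: {offenders[:5]}")


def finite_difference_derivatives(
        ts: SubjectTimeseries, factor: str | int) -> tuple[np.ndarray, np.ndarray]:
    """Annualized rate of change of one factor between consecutive visits.

    Returns ``(derivs, left_idx)`` where ``derivs`` has length
    ``n_rois * (n_times - 1)`` concatenated time-major (all regions of the
    first interval, then the second, ...) and ``left_idx`` gives, for each
    entry, the visit index of the interval's left endpoint, at which the
    design-matrix predictors are evaluated.
    """
    if ts.n_times < 2:
        raise ValueError("at least two time points are required")
    m = _factor_index(ts, factor)
    dt = np.diff(ts.times)  # years, strictly increasing by construction
    S = ts.values[m]  # (R, T)
    d = (S[:, 1:] - S[:, :-1]) / dt[None, :]  # (R, T-1)
    derivs = d.T.reshape(-1)  # time-major
    left_idx = np.repeat(np.arange(ts.n_times - 1), ts.n_rois)
    return derivs, left_idx


def spreading_term(S_m: np.ndarray, conn: Connectome) -> np.ndarray:
    """Inter-regional exchange sum_{j != i} C[j, i] * (S_j - S_i).

    ``S_m`` is (n_rois,) or (n_rois, n_times); the result has the same shape.
    """
    C = conn.matrix
    colsum = C.sum(axis=0)
    if S_m.ndim == 1:
        return C.T @ S_m - colsum * S_m
    return C.T @ S_m - colsum[:, None] * S_m


def build_design_matrix(ts: SubjectTimeseries, template: GeneExpressionTemplate,
                        conn: Connectome, target_factor: str | int) -> np.ndarray:
    """Predictor matrix turning model fitting into a linear regression.

    Shape ``[n_rois * (n_times - 1), n_factors + n_genes * n_factors + 1]``.
    Row (interval t, region i), time-major, holds:

    - columns ``0 .. n_factors-1``: ``S_i^n(t)`` for each source factor n;
    - gene block, gene-major then factor: column ``n_factors + k*n_factors + n``
      is ``G[k, i] * S_i^n(t)``;
    - last column: ``sum_{j != i} C[j, i] * (S_j^m(t) - S_i^m(t))``.

    With 976 genes and 6 factors this gives 5863 columns per target factor,
    5856 of them gene-modulation terms.
    """
    _check_alignment(ts, template, conn)
    if ts.n_times < 2:
        raise ValueError("at least two time points are required")
    m = _factor_index(ts, target_factor)
    F, R, T = ts.n_factors, ts.n_rois, ts.n_times
    K = template.n_genes

    Sl = np.transpose(ts.values[:, :, :-1], (2, 1, 0))  # (T-1, R, F)
    n_rows = R * (T - 1)

    base = Sl.reshape(n_rows, F)
    Gt = template.matrix.T  # (R, K)
    gene = (Gt[None, :, :, None] * Sl[:, :, None, :]).reshape(n_rows, K * F)
    spread = spreading_term(ts.values[m, :, :-1], conn)  # (R, T-1)
    spread = spread.T.reshape(n_rows, 1)
    return np.concatenate([base, gene, spread], axis=1)


def _drift(S: np.ndarray, coupling: list[np.ndarray], betas: np.ndarray,
           conn: Connectome) -> np.ndarray:
    """dS/dt for all factors at once; S is (F, R)."""
    F = S.shape[0]
    out = np.empty_like(S)
    St = S.T  # (R, F)
    for m in range(F):
        out[m] = (coupling[m] * St).sum(axis=1) + betas[m] * spreading_term(S[m], conn)
    return out


def simulate_forward(params: list[FactorParameterSet], s0: np.ndarray,
                     times: np.ndarray, template: GeneExpressionTemplate,
                     conn: Connectome, *, n_substeps: int = 1,
                     magnitude_bound: float = 1e6,
                     factor_names: list[str] | None = None,
                     subject_id: str = "subject") -> SubjectTimeseries:
    """Integrate the model forward with explicit Euler steps.

    One parameter set per factor, in factor order. By default one Euler step
    is taken per inter-visit interval, which makes the inverse problem exactly
    linear at the visit grid; ``n_substeps > 1`` refines the integration for
    robustness checks.
    """
    times = np.asarray(times, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    F, R = s0.shape
    if len(params) != F:
        raise ValueError(f"need one parameter set per factor ({F}), got {len(params)}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.all(np.isfinite(s0)):
        raise ValueError("initial state must be finite")
    if n_substeps < 1:
        raise ValueError("n_substeps must be >= 1")

    Gt = template.matrix.T  # (R, K)
    coupling = [p.alpha0[None, :] + Gt @ p.alpha_gene for p in params]  # (R, F) each
    betas = np.array([p.beta_spread for p in params])

    if factor_names is None:
        factor_names = [p.target_factor for p in params]

    values = np.empty((F, R, times.size))
    values[:, :, 0] = s0
    S = s0.copy()
    for t in range(times.size - 1):
        h = (times[t + 1] - times[t]) / n_substeps
        for sub in range(n_substeps):
            S = S + h * _drift(S, coupling, betas, conn)
            if not np.all(np.isfinite(S)) or np.max(np.abs(S)) > magnitude_bound:
                raise SimulationUnstableError(
                    f"subject {subject_id!r}: state magnitude exceeded "
                    f"{magnitude_bound:g} at step {t} (substep {sub})",
                    step=t, subject=subject_id)
        values[:, :, t + 1] = S
    return SubjectTimeseries(values=values, times=times,
                             factor_names=list(factor_names),
                             region_ids=list(template.region_ids),
                             subject_id=subject_id)


def r2_score(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    Undefined (NaN) when the observed vector has zero variance.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("observed and predicted must share a length >= 2")
    ss_tot = np.sum((observed - observed.mean()) ** 2)
    if ss_tot == 0:
        return float("nan")
    ss_res = np.sum((observed - predicted) ** 2)
    return float(1.0 - ss_res / ss_tot)
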