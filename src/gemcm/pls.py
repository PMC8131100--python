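"""Population analysis: stability filtering, behavioural PLS, resampling.

The subjects x parameters block of fitted gene-modulation coefficients is
first reduced to the parameters whose across-subject mean is stably nonzero
(t-based confidence interval excluding zero). The retained block is then
related to per-subject cognitive slopes by behavioural partial least squares:
both blocks are z-scored column-wise, the cross-block correlation matrix is
decomposed by SVD, component significance is assessed by permuting subject
rows of the cognitive block, and the reliability of each parameter's salience
on a significant component is quantified by its bootstrap ratio (salience /
bootstrap SE), with |ratio| > 2.58 marking a reliable contributor at roughly
the 99% level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import svd as _svd

__all__ = ["stability_filter", "svd_pls", "permutation_component_test",
           "bootstrap_ratios", "rank_genes", "BehavioralPLS", "PLSResults"]


def stability_filter(params: np.ndarray, ci_level: float = 0.99) -> np.ndarray:
    """Indices of parameters whose across-subject mean CI excludes zero.

    The CI is the t-based interval mean +/- t_{(1+ci)/2, n-1} * SE. A
    parameter with zero across-subject variance is kept when its common value
    is nonzero (the interval is a point away from zero) and dropped otherwise.
    """
    params = np.asarray(params, dtype=float)
    n = params.shape[0]
    if n < 3:
        raise ValueError("stability filtering needs at least 3 subjects")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    mean = params.mean(axis=0)
    se = params.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
    lo, hi = mean - tcrit * se, mean + tcrit * se
    keep = (lo > 0) | (hi < 0)
    degenerate = se == 0
    keep[degenerate] = mean[degenerate] != 0
    return np.where(keep)[0]


def _zscore_block(block: np.ndarray, name: str) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores (population SD) and the surviving column indices."""
    mean = block.mean(axis=0)
    sd = block.std(axis=0)
    ok = sd > 0
    if not np.all(ok):
        warnings.warn(f"{name}: excluding {int((~ok).sum())} zero-variance "
                      f"column(s) before correlation", stacklevel=3)
    z = (block[:, ok] - mean[ok]) / sd[ok]
    return z, np.where(ok)[0]


def _cross_svd(zp: np.ndarray, zq: np.ndarray):
    n = zp.shape[0]
    R = zp.T @ zq / n  # cross-block correlation (blocks are z-scored)
    U, s, Vt = _svd(R, full_matrices=False)
    return U, s, Vt.T


def _orient(U: np.ndarray, V: np.ndarray):
    """Flip each component so its largest-|loading| score loads positively."""
    for c in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, c])))
        if V[j, c] < 0:
            V[:, c] *= -1.0
            U[:, c] *= -1.0
    return U, V


@dataclass
class PLSResults:
    """Behavioural-PLS decomposition with permutation and bootstrap inference."""

    singular_values: np.ndarray
    explained_variance: np.ndarray
    saliences: np.ndarray          # parameters x components
    score_loadings: np.ndarray     # scores x components
    param_indices: np.ndarray      # columns of the input block used
    score_indices: np.ndarray
    component_pvalues: np.ndarray | None = None
    bootstrap_ratio: np.ndarray | None = None   # for tested_component
    tested_component: int | None = None
    selected_params: np.ndarray | None = None   # indices into param_indices space
    stable_param_indices: np.ndarray | None = None
    param_labels: list | None = None
    score_names: list | None = None
    n_perm: int = 0
    n_boot: int = 0

    @property
    def n_components(self) -> int:
        return self.singular_values.size

    def significant_components(self, alpha: float = 0.05) -> np.ndarray:
        if self.component_pvalues is None:
            return np.array([], dtype=int)
        return np.where(self.component_pvalues < alpha)[0]

    def summary(self) -> str:
        lines = ["Behavioural PLS",
                 f"  parameters: {self.saliences.shape[0]}, "
                 f"scores: {self.score_loadings.shape[0]}, "
                 f"components: {self.n_components}"]
        lines.append("  comp  singular  expl.var   p(perm)")
        for c in range(self.n_components):
            p = ("      -" if self.component_pvalues is None
                 else f"{self.component_pvalues[c]:.4f}")
            lines.append(f"  {c:>4}  {self.singular_values[c]:8.4f}  "
                         f"{self.explained_variance[c]:8.3f}   {p}")
        if self.bootstrap_ratio is not None:
            nsel = 0 if self.selected_params is None else self.selected_params.size
            lines.append(f"  bootstrap (component {self.tested_component}, "
                         f"n_boot={self.n_boot}): {nsel} reliable parameter(s)")
        return "\n".join(lines)


def svd_pls(params: np.ndarray, slopes: np.ndarray) -> PLSResults:
    """SVD of the cross-block correlation between parameters and slopes."""
    params = np.asarray(params, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    if params.shape[0] != slopes.shape[0]:
        raise ValueError("parameter and slope blocks must share subjects")
    if np.isnan(params).any() or np.isnan(slopes).any():
        raise ValueError("missing values must be excluded upstream")
    zp, pidx = _zscore_block(params, "parameter block")
    zq, qidx = _zscore_block(slopes, "slope block")
    if zp.shape[1] == 0 or zq.shape[1] == 0:
        raise ValueError("a block lost all columns to zero variance")
    U, s, V = _cross_svd(zp, zq)
    U, V = _orient(U, V)
    s2 = s ** 2
    ev = s2 / s2.sum() if s2.sum() > 0 else np.zeros_like(s2)
    return PLSResults(singular_values=s, explained_variance=ev,
                      saliences=U, score_loadings=V,
                      param_indices=pidx, score_indices=qidx)


def permutation_component_test(params: np.ndarray, slopes: np.ndarray,
                               n_perm: int = 10000, seed: int = 0) -> np.ndarray:
    """Add-one permutation p-value per component.

    Subject rows of the slope block are permuted; p_i = (1 + #{perm s_i >=
    observed s_i}) / (n_perm + 1), so p-values lie in [1/(n_perm+1), 1].
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    params = np.asarray(params, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    zp, _ = _zscore_block(params, "parameter block")
    zq, _ = _zscore_block(slopes, "slope block")
    _, s_obs, _ = _cross_svd(zp, zq)
    rng = np.random.default_rng(seed)
    n = zp.shape[0]
    exceed = np.zeros_like(s_obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        zq_p = zq[perm]
        _, s_p, _ = _cross_svd(zp, zq_p)
        exceed += s_p >= s_obs
    return (1.0 + exceed) / (n_perm + 1.0)


def _procrustes_rotation(U_ref: np.ndarray, U_boot: np.ndarray) -> np.ndarray:
    """Orthogonal rotation Q minimizing ||U_boot Q - U_ref||_F."""
    A, _, Bt = _svd(U_boot.T @ U_ref, full_matrices=False)
    return A @ Bt


def bootstrap_ratios(params: np.ndarray, slopes: np.ndarray, component: int = 0,
                     n_boot: int = 10000, seed: int = 0,
                     threshold: float = 2.58, procrustes: bool = True,
                     max_redraws: int = 1000):
    """Salience / bootstrap-SE ratio per parameter, for one component.

    Subjects are resampled with replacement; each bootstrap decomposition is
    aligned to the original saliences by an orthogonal Procrustes rotation
    (sign alignment when ``procrustes`` is False) before accumulating the SE.
    Returns ``(ratios, selected_indices, n_redrawn)``; parameters with a
    degenerate zero bootstrap SE get an infinite ratio and are reported but
    flagged by the +/-inf value.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    base = svd_pls(params, slopes)
    if not 0 <= component < base.n_components:
        raise ValueError(f"component {component} out of range")
    params_used = np.asarray(params, dtype=float)[:, base.param_indices]
    slopes_used = np.asarray(slopes, dtype=float)[:, base.score_indices]
    n = params_used.shape[0]
    rng = np.random.default_rng(seed)

    boots = np.empty((n_boot, base.saliences.shape[0]))
    n_redrawn = 0
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            pb, qb = params_used[idx], slopes_used[idx]
            if np.all(pb.std(axis=0) > 0) and np.all(qb.std(axis=0) > 0):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap sample")
        zp = (pb - pb.mean(axis=0)) / pb.std(axis=0)
        zq = (qb - qb.mean(axis=0)) / qb.std(axis=0)
        Ub, sb, Vb = _cross_svd(zp, zq)
        if procrustes:
            Q = _procrustes_rotation(base.saliences, Ub)
            Ub = Ub @ Q
        else:
            signs = np.sign(np.einsum("pc,pc->c", Ub, base.saliences))
            signs[signs == 0] = 1.0
            Ub = Ub * signs[None, :]
        boots[b] = Ub[:, component]

    se = boots.std(axis=0, ddof=1)
    sal = base.saliences[:, component]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(se > 0, sal / np.where(se > 0, se, 1.0),
                          np.sign(sal) * np.inf)
    selected = np.where(np.abs(ratios) > threshold)[0]
    return ratios, selected, n_redrawn


def rank_genes(labels: list, saliences: np.ndarray, ratios: np.ndarray,
               selected: np.ndarray) -> pd.DataFrame:
    """Table of selected parameters sorted by |salience| (ties by label)."""
    rows = []
    for j in selected:
        gene, src, tgt = labels[j]
        rows.append({"gene": gene, "source_factor": src, "target_factor": tgt,
                     "salience": saliences[j], "bootstrap_ratio": ratios[j]})
    df = pd.DataFrame(rows, columns=["gene", "source_factor", "target_factor",
                                     "salience", "bootstrap_ratio"])
    if len(df):
        df["_abs"] = df["salience"].abs()
        df = (df.sort_values(["_abs", "gene", "source_factor", "target_factor"],
                             ascending=[False, True, True, True])
                .drop(columns="_abs").reset_index(drop=True))
    return df


class BehavioralPLS:
    """Behavioural PLS relating gene-imaging parameters to cognitive slopes.

    Parameters
    ----------
    params : (subjects, p) array
        Typically the stability-filtered gene-modulation block.
    slopes : (subjects, q) array
        Per-subject cognitive slopes (score points per year).
    param_labels, score_names : optional label lists matching the columns.
    """

    def __init__(self, params, slopes, param_labels=None, score_names=None):
        self.params = np.asarray(params, dtype=float)
        self.slopes = np.asarray(slopes, dtype=float)
        if self.params.shape[0] != self.slopes.shape[0]:
            raise ValueError("blocks must share the subject dimension")
        self.param_labels = param_labels
        self.score_names = score_names

    def fit(self, n_perm: int = 10000, n_boot: int = 10000, seed: int = 0,
            threshold: float = 2.58, alpha: float = 0.05,
            procrustes: bool = True) -> PLSResults:
        """Decompose, test components by permutation, bootstrap the first
        significant component (none significant: no bootstrap stage)."""
        res = svd_pls(self.params, self.slopes)
        res.param_labels = self.param_labels
        res.score_names = self.score_names
        res.n_perm = n_perm
        res.component_pvalues = permutation_component_test(
            self.params, self.slopes, n_perm=n_perm, seed=seed)
        sig = res.significant_components(alpha)
        if sig.size:
            comp = int(sig[0])
            ratios, selected, _ = bootstrap_ratios(
                self.params, self.slopes, component=comp, n_boot=n_boot,
                seed=seed + 1, threshold=threshold, procrustes=procrustes)
            res.bootstrap_ratio = ratios
            res.tested_component = comp
            res.selected_params = selected
            res.n_boot = n_boot
        return res
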