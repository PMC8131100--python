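"""Model and results objects for per-subject fitting.

``GEMCM`` bundles one subject's longitudinal imaging with the expression
template and connectome; ``fit`` runs one horseshoe regression per target
factor (derivatives on design matrix) and returns a ``GEMCMResults`` carrying
the per-factor parameter sets, posterior uncertainty, in-sample R2 and a
``summary()`` table. ``fit_cohort`` maps the same fit over a list of subjects
with a deterministic per-subject/per-factor seed fan-out, and
``parameter_matrix`` stacks the fitted gene-modulation coefficients across
factors into the subjects x parameters block used by the population analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (Connectome, FactorParameterSet, GeneExpressionTemplate,
                        SubjectTimeseries, parameter_labels)
from .horseshoe import HorseshoeConfig, PosteriorSummary, horseshoe_fit
from .mcm import build_design_matrix, finite_difference_derivatives, r2_score

__all__ = ["GEMCM", "GEMCMResults", "fit_subject", "fit_cohort",
           "parameter_matrix", "gene_parameter_labels", "subseed"]


def subseed(seed: int, *path: int) -> int:
    """Deterministic sub-seed for a (stage, subject, factor, ...) path.

    Fans one global seed out through ``numpy.random.SeedSequence`` so that
    per-subject parallelism or reordering cannot change results. The result
    is always below 2**31.
    """
    return int(np.random.SeedSequence([int(seed), *map(int, path)])
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class GEMCMResults:
    """Fitted per-factor parameters and fit diagnostics for one subject."""

    subject_id: str
    params: list[FactorParameterSet]
    posteriors: list[PosteriorSummary]
    r2: np.ndarray  # per target factor
    factor_names: list[str]
    gene_ids: list[str]

    @property
    def mean_r2(self) -> float:
        return float(np.nanmean(self.r2))

    def flat_params(self) -> np.ndarray:
        """All per-factor parameter vectors concatenated in factor order."""
        return np.concatenate([p.flatten() for p in self.params])

    def gene_params(self) -> np.ndarray:
        """Gene-modulation coefficients only, stacked across target factors.

        Length ``n_factors * n_genes * n_factors`` (5856-per-factor layout
        when genes=976, factors=6), gene-major within each target factor.
        """
        return np.concatenate([p.alpha_gene.reshape(-1) for p in self.params])

    def summary(self) -> str:
        lines = [f"GEMCM fit: subject {self.subject_id}",
                 f"  factors: {len(self.factor_names)}, genes: {len(self.gene_ids)}",
                 f"  coefficients per factor: {self.params[0].flatten().size}",
                 f"  mean in-sample R2: {self.mean_r2:.4f}",
                 "", "  target factor      R2    |beta_spread|  sampler"]
        for m, name in enumerate(self.factor_names):
            lines.append(
                f"  {name:<15} {self.r2[m]:6.3f}  "
                f"{abs(self.params[m].beta_spread):12.4g}  "
                f"{self.posteriors[m].sampler_mode_used}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of every coefficient with labels and posterior SD."""
        frames = []
        for m, name in enumerate(self.factor_names):
            labels = parameter_labels(self.gene_ids, self.factor_names, name)
            frames.append(pd.DataFrame({
                "target_factor": name,
                "parameter": labels,
                "estimate": self.params[m].flatten(),
                "posterior_sd": self.posteriors[m].coef_sd,
            }))
        return pd.concat(frames, ignore_index=True)


class GEMCM:
    """Gene-expression-modulated causal model for one subject's trajectories.

    Parameters
    ----------
    timeseries : SubjectTimeseries
        Factors x regions x visits imaging array with visit times in years.
    template : GeneExpressionTemplate
        Genes x regions z-scored expression.
    connectome : Connectome
        Nonnegative region coupling matrix (zero diagonal).
    """

    def __init__(self, timeseries: SubjectTimeseries,
                 template: GeneExpressionTemplate, connectome: Connectome):
        if timeseries.n_times < 2:
            raise ValueError("fitting requires at least two time points")
        self.timeseries = timeseries
        self.template = template
        self.connectome = connectome
        # eagerly validated alignment via a probe design-matrix header build
        from .mcm import _check_alignment
        _check_alignment(timeseries, template, connectome)

    def design_matrix(self, target_factor: str | int) -> np.ndarray:
        return build_design_matrix(self.timeseries, self.template,
                                   self.connectome, target_factor)

    def fit(self, cfg: HorseshoeConfig | None = None) -> GEMCMResults:
        """One horseshoe regression per target factor; seeds fan out per factor."""
        cfg = cfg or HorseshoeConfig()
        ts = self.timeseries
        params, posteriors, r2s = [], [], []
        for m, name in enumerate(ts.factor_names):
            y, _ = finite_difference_derivatives(ts, m)
            X = self.design_matrix(m)
            fcfg = HorseshoeConfig(
                n_burn=cfg.n_burn, n_keep=cfg.n_keep,
                seed=subseed(cfg.seed, m), sampler_mode=cfg.sampler_mode,
                keep_samples=cfg.keep_samples, n_chains=cfg.n_chains)
            post = horseshoe_fit(X, y, fcfg)
            params.append(FactorParameterSet.from_flat(
                post.coef_mean, self.template.n_genes, ts.n_factors, name))
            posteriors.append(post)
            r2s.append(r2_score(y, X @ post.coef_mean))
        return GEMCMResults(subject_id=ts.subject_id, params=params,
                            posteriors=posteriors, r2=np.array(r2s),
                            factor_names=list(ts.factor_names),
                            gene_ids=list(self.template.gene_ids))


def fit_subject(ts: SubjectTimeseries, template: GeneExpressionTemplate,
                conn: Connectome,
                cfg: HorseshoeConfig | None = None) -> GEMCMResults:
    """Functional wrapper: ``GEMCM(ts, template, conn).fit(cfg)``."""
    return GEMCM(ts, template, conn).fit(cfg)


def fit_cohort(subjects: list[SubjectTimeseries],
               template: GeneExpressionTemplate, conn: Connectome,
               cfg: HorseshoeConfig | None = None, *,
               progress: bool = False) -> list[GEMCMResults]:
    """Fit every subject; subject s, factor m uses sub-seed (seed, s, m)."""
    cfg = cfg or HorseshoeConfig()
    results = []
    iterator = enumerate(subjects)
    if progress:
        import sys
        print(f"fitting {len(subjects)} subjects", file=sys.stderr)
    for s, ts in iterator:
        scfg = HorseshoeConfig(n_burn=cfg.n_burn, n_keep=cfg.n_keep,
                               seed=subseed(cfg.seed, s),
                               sampler_mode=cfg.sampler_mode,
                               keep_samples=cfg.keep_samples,
                               n_chains=cfg.n_chains)
        results.append(fit_subject(ts, template, conn, scfg))
        if progress:
            import sys
            print(f"  subject {ts.subject_id}: mean R2 = "
                  f"{results[-1].mean_r2:.3f}", file=sys.stderr)
    return results


def gene_parameter_labels(gene_ids: list[str],
                          factor_names: list[str]) -> list[tuple[str, str, str]]:
    """(gene, source factor, target factor) labels in gene_params() order."""
    labels = []
    for target in factor_names:
        for g in gene_ids:
            for src in factor_names:
                labels.append((g, src, target))
    return labels


def parameter_matrix(results: list[GEMCMResults]) -> tuple[np.ndarray, list[tuple[str, str, str]]]:
    """Subjects x parameters block of gene-modulation coefficients.

    Columns stack the gene blocks of all target factors (factor-major,
    then gene-major, then source factor) with (gene, source, target) labels.
    """
    if not results:
        raise ValueError("no fitted subjects")
    mat = np.stack([r.gene_params() for r in results])
    labels = gene_parameter_labels(results[0].gene_ids, results[0].factor_names)
    if mat.shape[1] != len(labels):
        raise ValueError("label/column count mismatch")
    return mat, labels
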