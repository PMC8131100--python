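"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator produces (i) a spatially autocorrelated gene-expression
template sampled from a Gaussian process over random 3-D region coordinates,
(ii) a sparse nonnegative log-normal connectome, (iii) per-subject
longitudinal trajectories integrated with the model's own forward dynamics
(forward Euler at the visit grid by default, so the inverse problem is exact
at zero noise) plus i.i.d. observation noise, and (iv) cognitive visit tables
whose per-subject slopes are, by construction, a noisy linear function of the
subject's gene-modulation parameters projected onto a latent direction.

All parameter supports are shared across subjects (each subject's active
coefficients jitter around common base values), which is what makes
population-level stability filtering and PLS recovery meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (Connectome, FactorParameterSet, GeneExpressionTemplate,
                        SubjectTimeseries)
from .mcm import simulate_forward
from .preprocess import COGNITIVE_SCORES

__all__ = ["SyntheticCohortConfig", "SyntheticCohort", "gen_connectome",
           "gen_gene_expression", "gen_cohort", "DEFAULT_FACTORS"]

DEFAULT_FACTORS = ["abeta", "tau", "cbf", "metabolism", "activity", "gm_density"]

# per-score multiplier mapping the latent projection to slope units
# (points per year), roughly matching the dynamic range of each instrument
_DEFAULT_COG_SCALES = (-2.0, 3.0, 4.0, -0.1, -0.1)


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    The defaults define the reference desk-scale cohort: 40 subjects with
    5 annual visits over 30 regions and 50 genes, a sparse shared truth of
    20 active gene-modulation coefficients at scale 0.1, and moderate
    observation noise relative to signals of order one.
    """

    n_subjects: int = 40
    n_rois: int = 30
    n_genes: int = 50
    n_factors: int = 6
    n_timepoints: int = 5
    dt_years: float = 1.0
    connectome_density: float = 0.3
    gene_spatial_lengthscale: float = 30.0  # mm, vs. coordinates in [0, 100]^3
    n_active_params: int = 20
    effect_scale: float = 0.1
    obs_noise_sd: float = 0.01
    cog_noise_sd: float = 0.05  # in latent-projection units
    n_cog_scores: int = 5
    seed: int = 0
    # secondary conditions
    alpha0_scale: float = 0.02        # SD of baseline factor-factor couplings
    spread_scale: float = 0.02        # scale of the spreading coefficients
    subject_sd_frac: float = 0.3      # independent across-subject jitter of active params
    latent_frac: float = 0.5          # fraction of active params the latent loads
    latent_strength_frac: float = 1.0  # severity-axis SD, as multiple of effect_scale
    n_cog_visits: int = 7
    cog_visit_spacing: float = 1.0    # years
    magnitude_bound: float = 1e3
    n_substeps: int = 1

    def __post_init__(self):
        for name in ("n_subjects", "n_rois", "n_genes", "n_factors",
                     "n_timepoints", "n_cog_scores", "n_cog_visits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_factors < 2:
            raise ValueError("n_factors must be >= 2 for interaction terms")
        if not 0 < self.connectome_density <= 1:
            raise ValueError("connectome_density must be in (0, 1]")
        if self.n_active_params > self.n_genes * self.n_factors ** 2:
            raise ValueError("n_active_params exceeds the gene-parameter space")
        if self.dt_years <= 0 or self.gene_spatial_lengthscale <= 0:
            raise ValueError("dt_years and gene_spatial_lengthscale must be > 0")
        if self.obs_noise_sd < 0 or self.cog_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    template: GeneExpressionTemplate
    region_coords: np.ndarray
    connectome: Connectome
    subjects: list[SubjectTimeseries]
    true_params: list[list[FactorParameterSet]]  # per subject, per factor
    cognitive: pd.DataFrame  # long format: subject_id, age, score_name, value
    true_latent: np.ndarray  # over the stacked gene-modulation space
    true_slopes: np.ndarray  # subjects x scores, noiseless-visit slopes
    active_indices: np.ndarray  # indices into the stacked gene space
    latent_indices: np.ndarray  # subset of active_indices the latent loads
    score_names: list[str] = field(default_factory=list)

    def true_gene_params(self) -> np.ndarray:
        """Subjects x (n_factors^2 * n_genes) stacked gene-modulation truth."""
        return np.stack([
            np.concatenate([p.alpha_gene.reshape(-1) for p in per_subject])
            for per_subject in self.true_params])


def gen_connectome(n_rois: int, density: float, seed: int) -> Connectome:
    """Sparse symmetric log-normal connectome with zero diagonal.

    Each upper-triangle edge exists independently with probability
    ``density``; existing edges get log-normal weights mimicking the heavy
    tail of streamline counts.
    """
    if n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_rois, k=1)
    present = rng.random(iu[0].size) < density
    weights = np.where(present, rng.lognormal(0.0, 1.0, iu[0].size), 0.0)
    C = np.zeros((n_rois, n_rois))
    C[iu] = weights
    C = C + C.T
    return Connectome(C, [f"roi{i:03d}" for i in range(n_rois)])


def gen_gene_expression(n_genes: int, n_rois: int, lengthscale: float,
                        seed: int) -> tuple[GeneExpressionTemplate, np.ndarray, np.ndarray]:
    """Spatially autocorrelated expression maps over random 3-D coordinates.

    Regions get uniform coordinates in [0, 100]^3 mm; each gene is a draw
    from a zero-mean Gaussian process with squared-exponential kernel of the
    given lengthscale at those coordinates, z-scored across regions.
    Returns ``(template, region_coords, raw_fields)`` where ``raw_fields``
    are the fields before z-scoring (for spatial-autocorrelation checks).
    """
    if n_genes < 1 or n_rois < 1:
        raise ValueError("n_genes and n_rois must be >= 1")
    if lengthscale <= 0:
        raise ValueError("lengthscale must be positive")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 100.0, size=(n_rois, 3))
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2.0 * lengthscale ** 2)) + 1e-8 * np.eye(n_rois)
    L = np.linalg.cholesky(K)
    raw = (L @ rng.standard_normal((n_rois, n_genes))).T  # genes x regions
    sd = raw.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    matrix = (raw - raw.mean(axis=1, keepdims=True)) / sd
    template = GeneExpressionTemplate(
        matrix, [f"gene{k:04d}" for k in range(n_genes)],
        [f"roi{i:03d}" for i in range(n_rois)])
    return template, coords, raw


def _draw_parameters(cfg: SyntheticCohortConfig, rng: np.random.Generator):
    """Shared sparse truth: supports, base values, latent direction."""
    F, K = cfg.n_factors, cfg.n_genes
    space = F * K * F  # stacked gene blocks over target factors
    active = np.sort(rng.choice(space, size=cfg.n_active_params, replace=False))
    signs = rng.choice([-1.0, 1.0], size=cfg.n_active_params)
    base = cfg.effect_scale * signs * rng.uniform(0.75, 1.25, cfg.n_active_params)

    n_loaded = max(1, int(round(cfg.latent_frac * cfg.n_active_params)))
    loaded = np.sort(rng.choice(cfg.n_active_params, size=n_loaded, replace=False))
    latent = np.zeros(space)
    latent[active[loaded]] = rng.choice([-1.0, 1.0], size=n_loaded)
    norm = np.linalg.norm(latent)
    if norm > 0:
        latent /= norm

    alpha0_base = rng.normal(0.0, cfg.alpha0_scale, size=(F, F))
    beta_base = np.abs(rng.normal(0.0, cfg.spread_scale, size=F))
    return active, base, latent, active[loaded], alpha0_base, beta_base


def _subject_params(cfg: SyntheticCohortConfig, rng: np.random.Generator,
                    active, base, latent, alpha0_base, beta_base,
                    factor_names) -> tuple[list[FactorParameterSet], np.ndarray]:
    """One subject's parameters: shared base values on the active support,
    plus a severity draw along the latent direction (the coordinated
    subject-to-subject variation the cognitive slopes read out), plus
    independent jitter."""
    F, K = cfg.n_factors, cfg.n_genes
    gene_vec = np.zeros(F * K * F)
    jitter = cfg.subject_sd_frac * cfg.effect_scale * rng.standard_normal(active.size)
    severity = rng.standard_normal()
    gene_vec[active] = base + jitter
    gene_vec += severity * cfg.latent_strength_frac * cfg.effect_scale * latent
    per_factor = gene_vec.reshape(F, K, F)  # target-major, gene, source
    params = [FactorParameterSet(alpha0=alpha0_base[m].copy(),
                                 alpha_gene=per_factor[m].copy(),
                                 beta_spread=float(beta_base[m]),
                                 target_factor=factor_names[m])
              for m in range(F)]
    return params, gene_vec


def gen_cohort(cfg: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a full cohort under the configured study conditions.

    Deterministic for a fixed config (including seed): every random stream is
    a child of one seed sequence, split per stage and per subject.
    """
    root = np.random.SeedSequence(cfg.seed)
    s_template, s_conn, s_truth, s_subjects, s_cog = root.spawn(5)

    template, coords, _ = gen_gene_expression(
        cfg.n_genes, cfg.n_rois, cfg.gene_spatial_lengthscale,
        int(s_template.generate_state(1)[0] % 2 ** 31))
    conn = gen_connectome(cfg.n_rois, cfg.connectome_density,
                          int(s_conn.generate_state(1)[0] % 2 ** 31))

    truth_rng = np.random.default_rng(s_truth)
    factor_names = (DEFAULT_FACTORS[:cfg.n_factors]
                    if cfg.n_factors <= len(DEFAULT_FACTORS)
                    else [f"factor{m}" for m in range(cfg.n_factors)])
    active, base, latent, loaded_idx, alpha0_base, beta_base = \
        _draw_parameters(cfg, truth_rng)

    times = np.arange(cfg.n_timepoints) * cfg.dt_years
    subjects, true_params, projections = [], [], []
    subj_seqs = s_subjects.spawn(cfg.n_subjects)
    for s in range(cfg.n_subjects):
        rng = np.random.default_rng(subj_seqs[s])
        params, gene_vec = _subject_params(
            cfg, rng, active, base, latent, alpha0_base, beta_base, factor_names)
        s0 = rng.uniform(0.5, 1.5, size=(cfg.n_factors, cfg.n_rois))
        ts = simulate_forward(params, s0, times, template, conn,
                              n_substeps=cfg.n_substeps,
                              magnitude_bound=cfg.magnitude_bound,
                              factor_names=factor_names,
                              subject_id=f"sub{s:03d}")
        if cfg.obs_noise_sd > 0:
            noisy = ts.values + rng.normal(0.0, cfg.obs_noise_sd, ts.values.shape)
            ts = SubjectTimeseries(noisy, ts.times, list(ts.factor_names),
                                   list(ts.region_ids), ts.subject_id)
        subjects.append(ts)
        true_params.append(params)
        projections.append(float(gene_vec @ latent))

    score_names = (COGNITIVE_SCORES[:cfg.n_cog_scores]
                   if cfg.n_cog_scores <= len(COGNITIVE_SCORES)
                   else [f"score{c}" for c in range(cfg.n_cog_scores)])
    scales = np.array([(_DEFAULT_COG_SCALES[c]
                        if c < len(_DEFAULT_COG_SCALES) else 1.0)
                       for c in range(cfg.n_cog_scores)])
    baselines = np.array([28.0, 10.0, 15.0, 0.0, 0.0][:cfg.n_cog_scores].copy()
                         if cfg.n_cog_scores <= 5 else np.zeros(cfg.n_cog_scores))

    cog_rng = np.random.default_rng(s_cog)
    rows = []
    true_slopes = np.empty((cfg.n_subjects, cfg.n_cog_scores))
    for s in range(cfg.n_subjects):
        age0 = cog_rng.uniform(60.0, 80.0)
        noise = cog_rng.normal(0.0, cfg.cog_noise_sd, cfg.n_cog_scores)
        slopes = scales * (projections[s] + noise)
        true_slopes[s] = slopes
        for v in range(cfg.n_cog_visits):
            age = age0 + v * cfg.cog_visit_spacing
            for c, name in enumerate(score_names):
                rows.append({"subject_id": f"sub{s:03d}", "age": age,
                             "score_name": name,
                             "value": baselines[c] + slopes[c] * (age - age0)})
    cognitive = pd.DataFrame(rows)

    return SyntheticCohort(
        config=cfg, template=template, region_coords=coords, connectome=conn,
        subjects=subjects, true_params=true_params, cognitive=cognitive,
        true_latent=latent, true_slopes=true_slopes, active_indices=active,
        latent_indices=loaded_idx, score_names=score_names)
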