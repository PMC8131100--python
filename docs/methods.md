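# Methods

## Model and regression formulation

The package models the annualized rate of change of each macroscopic factor
`m` at region `i` as the sum of (a) within-region factor–factor influences
whose coupling strengths are linearly modulated by the local z-scored
expression of every gene, and (b) diffusive exchange of factor `m` along
connectome edges:

    dS_i^m/dt = Σ_n (α0[n→m] + Σ_k α[k,n→m] G[k,i]) S_i^n
              + β^m Σ_{j≠i} C[j,i] (S_j^m − S_i^m)

Fitting uses finite differences between consecutive visits, divided by the
inter-visit interval in years, with all predictors evaluated at the left
endpoint of each interval (the explicit-Euler convention). Stacking the
regions of every interval time-major gives, per subject and target factor, a
derivative vector of length `n_rois · (n_times − 1)` and a design matrix
whose columns are ordered: baseline block (one column per source factor),
gene block (gene-major, then source factor), spreading column. The flattened
parameter vector uses the identical order, so trajectories generated by
forward Euler at the visit grid satisfy `derivs = X · θ` exactly — this
identity is the package's primary structural invariant and is tested to
1e−8.

Design decisions worth naming:

- **One scalar spreading coefficient per target factor.** The spreading term
  is `β^m · Σ_j C[j,i](S_j^m − S_i^m)` with a single unknown `β^m`. This
  yields `n_factors + n_genes·n_factors + 1` coefficients per factor (5863
  at 976 genes / 6 factors, 5856 of them gene-modulation terms), the count
  the rest of the pipeline is built around.
- **One anatomical connectome for all factors.** The `Connectome` type would
  admit per-factor matrices, but the default pipeline uses a single matrix.
- **Annualized derivatives.** Dividing by the visit interval makes
  parameters comparable across irregular visit schedules; their units are
  per-year.
- The imaging signals are used as-is (positive, order-one values); no
  z-scoring of `S` is applied before fitting.

## Horseshoe inference

Each per-factor regression is solved by Gibbs sampling of the horseshoe
hierarchy: Gaussian likelihood, `β_j ~ N(0, σ²τ²λ_j²)`, half-Cauchy priors
on the local scales `λ_j` and global scale `τ` (via inverse-gamma auxiliary
variables), Jeffreys prior on `σ²`. Defaults are 1000 burn-in iterations and
500 kept draws, whose mean is the point estimate; the posterior SD of the
kept draws is reported alongside. The conditional Gaussian draw of `β` uses
a p×p Cholesky when `p ≤ n` and the exact O(n²p) data-augmentation sampler
when `p > n` (mode `auto`); both target the same conditional and are tested
to agree within Monte-Carlo error. Columns of `X` are rescaled internally to
unit root-mean-square — not centered, because the model has no intercept —
and coefficients are mapped back; `y` is untouched. Local and global scales
are clamped to [1e−16, 1e16] to avoid overflow; non-finite draws raise a
sampler-divergence error rather than propagating. No convergence gate is
applied at the default fixed budget; split-chain R-hat is reported when
multiple chains are requested.

## Population analysis

Gene-modulation coefficients of all six target factors are stacked into a
subjects × parameters block. Parameters whose across-subject mean has a
t-based 99% CI excluding zero are retained (a parameter with zero
across-subject variance is kept iff its common value is nonzero). The
retained block and the subjects × 5 matrix of cognitive slopes (OLS of each
score against age; fewer than two usable visits leaves the slope undefined,
never zero-filled) are column z-scored and their p × q cross-correlation
matrix decomposed by SVD. Choices: correlation rather than covariance
(scores and parameters have incommensurate units); each component's sign is
oriented so its largest-|loading| cognitive score loads positively;
permutation inference shuffles subject rows of the cognitive block and uses
the add-one p-value `(1 + #{s_perm ≥ s_obs}) / (n_perm + 1)`, so p ∈
[1/(n_perm+1), 1]; only components with permutation p < 0.05 proceed to the
bootstrap; bootstrap resamples subjects with replacement, aligns each
resampled salience matrix to the original by an orthogonal Procrustes
rotation (sign-alignment available as a fallback), and thresholds
|salience / bootstrap SE| at 2.58 (≈ 99% two-sided if normal). Degenerate
zero-variance bootstrap columns trigger a redraw (counted); a zero bootstrap
SE yields an infinite ratio, reported but flagged.

## Transcriptome preparation

Regional templates are built from point samples by Gaussian-kernel
regression (normalized weights `exp(−d²/2σ²)`; predictions are convex
combinations of sample values; a query beyond kernel support falls back to
the nearest sample with a counted warning). The kernel bandwidth σ is a
required explicit argument everywhere — there is no privileged default —
and `loocv_sigma_sweep` evaluates a candidate grid. Probe selection uses
leave-one-out prediction accuracy measured as the Pearson correlation
between observed and held-out-predicted values; probes with < 3 samples or
zero variance are ineligible (−inf accuracy), ties break to the lowest probe
index. Regional aggregation averages samples within a region, fills
sample-free regions by kernel regression at region centroids, and z-scores
each gene across regions with the population (divisor-n) SD; genes constant
across regions cannot be z-scored and are excluded, flagged as degenerate.

## Cohort screening

The multivariate outlier screen flags subjects whose squared Mahalanobis
distance to the sample mean exceeds the chi-square upper-α quantile
(default α = 0.05); a singular covariance is ridge-regularized with a logged
warning. Missing-modality imputation follows trimmed scores regression with
an internal PCA: missing cells start at column means; each iteration fits a
rank-r PCA of the completed matrix, regresses every incomplete row's
component scores from its observed features only, and reconstructs the
missing features from those scores, iterating to a 1e−8 relative change
(rank chosen per iteration to reach 90% explained variance unless given).
The observed-cell reconstruction error is logged per iteration and is
non-increasing; non-convergence returns the best iterate with a warning.

## Synthetic cohorts: what they emulate, and what they do not

The generator's defaults define the reference desk-scale study: 40 subjects,
30 regions, 50 genes, 6 factors, 5 annual imaging visits, a 30%-dense
symmetric log-normal connectome (heavy-tailed weights mimicking streamline
counts), and gene maps drawn from a squared-exponential Gaussian process
over uniform 3-D region coordinates in a 100 mm box with a 30 mm
lengthscale, z-scored per gene. Trajectories are integrated with the model's
own forward dynamics at the visit grid (forward Euler, so the inverse
problem is exactly linear at zero noise; `n_substeps` refines the
integration for robustness checks), from initial states uniform in
[0.5, 1.5] to mimic normalized imaging signals, with i.i.d. Gaussian
observation noise of SD 0.01 on signals of order one.

The ground truth is sparse and population-structured: 20 gene-modulation
coefficients (of 1800) are active on a support shared by all subjects, with
base magnitudes ~0.1 and random signs; baseline couplings have SD 0.02 and
spreading coefficients are nonnegative with scale 0.02 — small enough that
5-visit Euler trajectories stay bounded, large enough that the derivative
signal dominates the noise. Subject-to-subject variation has two parts:
independent jitter (SD 0.03) on every active coefficient, and a coordinated
"severity" draw along a unit latent direction supported on half of the
active coefficients. Cognitive slopes are constructed as per-score multiples
of the subject's latent projection plus projection-scale noise (SD 0.05),
and visit tables realize those slopes exactly over 7 annual visits — so at
zero cognitive noise the slopes are exactly collinear with the projections.
The severity axis is what makes population recovery well-posed: without it,
each loaded parameter's correlation with the projection is bounded by
1/√(n_loaded) regardless of noise, and no selection rule could reach high
sensitivity at n = 40.

What passing these tests does **not** show about real data: real imaging
trajectories do not follow the fitted model's own discretization, real
parameter supports are not shared exactly across subjects, cognitive visits
carry per-visit measurement error rather than exactly linear trajectories,
and real effect sizes and noise levels are unknown — the defaults here are
declared, not inferred. One consequence observed even on synthetic data:
when the population pipeline is run on *estimated* (rather than generated)
parameters, correlated design columns let the severity signal leak into many
estimated coefficients, which the bootstrap then — correctly — flags as
slope-associated; selection specificity on estimated parameters is therefore
substantially worse than on the generating parameters. Interpretation of
selected parameters on real cohorts should bear this leakage in mind.

## Problem sizes and numerical settings

The reference analyses use the cohort defaults above; the per-subject fit is
6 regressions of 120 observations × 307 coefficients at the default 1000+500
MCMC budget (a few seconds per subject), and population inference uses 1000
permutations and 1000 bootstrap draws in the reference runs (10,000 is the
recommended production setting and the CLI default). Resampling calibration
checks use 500 null repetitions at 199 permutations. All randomness flows
from one seed through `numpy.random.SeedSequence` splitting, keyed by stage,
subject and factor indices, so subject-level parallelism or reordering
cannot change results; every derived seed stays below 2³¹.

## Known limitations

- The forward-Euler generator/fitting pair makes the inverse problem exactly
  linear by construction; finer integration (`n_substeps > 1`) breaks the
  exact identity and is provided for robustness experiments only.
- The stability filter's t-based CI assumes approximately normal
  across-subject parameter means; no bootstrap CI variant is provided.
- Cognitive slopes are unadjusted OLS against age (no covariates).
- The ring-plot style visualization of gene contributions is not included;
  `rank_genes` returns the underlying table.
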