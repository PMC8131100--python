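"""Core data containers for gene-expression-modulated causal modelling.

The model couples three kinds of regional data: a genes x regions expression
template (z-scored per gene across regions), a nonnegative anatomical
connectome, and per-subject longitudinal multimodal imaging trajectories
(factors x regions x visits). Parameter sets hold, per target factor, the
baseline factor-factor interaction terms, the gene-modulation terms, and a
single inter-regional spreading coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class AlignmentError(ValueError):
    """Region or gene identifiers of two inputs do not match."""


class SimulationUnstableError(RuntimeError):
    """Forward integration exceeded the configured magnitude bound."""

    def __init__(self, message: str, step: int | None = None,
                 subject: str | None = None):
        super().__init__(message)
        self.step = step
        self.subject = subject


@dataclass
class GeneExpressionTemplate:
    """Genes x regions expression matrix, z-scored per gene across regions."""

    matrix: np.ndarray
    gene_ids: list[str]
    region_ids: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-D (genes x regions)")
        if self.matrix.shape != (len(self.gene_ids), len(self.region_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.region_ids)} regions")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[1]

    def validate_zscored(self, atol: float = 1e-8) -> None:
        """Raise if any gene deviates from mean 0 / SD 1 across regions."""
        if self.n_genes == 0:
            return
        mu = self.matrix.mean(axis=1)
        sd = self.matrix.std(axis=1)
        if np.any(np.abs(mu) > atol) or np.any(np.abs(sd - 1.0) > atol):
            bad = np.where((np.abs(mu) > atol) | (np.abs(sd - 1.0) > atol))[0]
            raise ValueError(
                f"genes not z-scored across regions: {[self.gene_ids[i] for i in bad[:5]]}")


@dataclass
class Connectome:
    """Regions x regions nonnegative coupling matrix with zero diagonal."""

    matrix: np.ndarray
    region_ids: list[str]
    row_normalized: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.region_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"connectome must be {n}x{n}, got {self.matrix.shape}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("connectome contains non-finite values")
        if np.any(self.matrix < 0):
            raise ValueError("connectome contains negative weights")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("connectome diagonal must be zero")

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]

    def normalized_rows(self) -> "Connectome":
        """Return a copy with each nonzero row scaled to unit sum."""
        rowsum = self.matrix.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        return Connectome(self.matrix / rowsum, list(self.region_ids),
                          row_normalized=True)


@dataclass
class SubjectTimeseries:
    """One subject's factors x regions x visits imaging array.

    ``times`` are acquisition ages/times in years and must be strictly
    increasing. At least two visits are needed to form one finite-difference
    interval; cohort-level screens may require more.
    """

    values: np.ndarray
    times: np.ndarray
    factor_names: list[str]
    region_ids: list[str]
    subject_id: str = "subject"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        nf, nr = len(self.factor_names), len(self.region_ids)
        if self.values.shape != (nf, nr, self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({nf} factors, {nr} regions, {self.times.size} times)")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("acquisition times must be strictly increasing")

    @property
    def n_factors(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def n_times(self) -> int:
        return self.values.shape[2]


@dataclass
class FactorParameterSet:
    """Parameters governing the rate of change of one target factor.

    ``alpha0[n]`` is the baseline influence of source factor ``n``,
    ``alpha_gene[k, n]`` the modulation of that influence by gene ``k``
    (so the effective coupling at region i is
    ``alpha0[n] + sum_k alpha_gene[k, n] * G[k, i]``), and ``beta_spread``
    scales the inter-regional exchange along connectome edges.
    """

    alpha0: np.ndarray
    alpha_gene: np.ndarray
    beta_spread: float
    target_factor: str

    def __post_init__(self):
        self.alpha0 = np.asarray(self.alpha0, dtype=float)
        self.alpha_gene = np.asarray(self.alpha_gene, dtype=float)
        if self.alpha0.ndim != 1:
            raise ValueError("alpha0 must be 1-D (one entry per source factor)")
        if self.alpha_gene.ndim != 2 or (
                self.alpha_gene.size and self.alpha_gene.shape[1] != self.alpha0.size):
            raise ValueError("alpha_gene must be n_genes x n_factors")
        self.beta_spread = float(self.beta_spread)

    @property
    def n_factors(self) -> int:
        return self.alpha0.size

    @property
    def n_genes(self) -> int:
        return self.alpha_gene.shape[0]

    def flatten(self) -> np.ndarray:
        """Flatten to the design-matrix column order.

        Order: ``alpha0`` (n_factors), then the gene block gene-major
        (``alpha_gene[0, :], alpha_gene[1, :], ...``), then ``beta_spread``.
        Length ``n_factors + n_genes * n_factors + 1``.
        """
        return np.concatenate([
            self.alpha0,
            self.alpha_gene.reshape(-1),
            [self.beta_spread],
        ])

    @classmethod
    def from_flat(cls, theta: np.ndarray, n_genes: int, n_factors: int,
                  target_factor: str) -> "FactorParameterSet":
        theta = np.asarray(theta, dtype=float)
        expected = n_factors + n_genes * n_factors + 1
        if theta.size != expected:
            raise ValueError(f"expected {expected} parameters, got {theta.size}")
        return cls(
            alpha0=theta[:n_factors].copy(),
            alpha_gene=theta[n_factors:-1].reshape(n_genes, n_factors).copy(),
            beta_spread=float(theta[-1]),
            target_factor=target_factor,
        )


def parameter_labels(gene_ids: list[str], factor_names: list[str],
                     target_factor: str) -> list[str]:
    """Column labels matching :meth:`FactorParameterSet.flatten` order."""
    labels = [f"alpha0[{n}->{target_factor}]" for n in factor_names]
    labels += [f"alpha[{g}:{n}->{target_factor}]"
               for g in gene_ids for n in factor_names]
    labels.append(f"beta_spread[{target_factor}]")
    return labels
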