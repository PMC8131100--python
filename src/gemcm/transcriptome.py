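"""Spatial preparation of a regional expression template from point samples.

Tissue samples carry 3-D coordinates and per-probe expression values; regional
expression is obtained by Gaussian-kernel regression (a normalized
radial-basis weighted mean whose weights fall off with distance), a
leave-one-out cross-validation picks the best-predicting probe per gene, and
regional means are z-scored per gene across regions to form the template.

The kernel bandwidth ``sigma`` has no privileged value and is a required
argument everywhere; ``loocv_sigma_sweep`` evaluates a candidate grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .datatypes import GeneExpressionTemplate

__all__ = ["ExpressionSampleSet", "kernel_regress", "select_probe_loocv",
           "loocv_sigma_sweep", "build_template", "read_samples_tsv",
           "NoValidProbeError"]


class NoValidProbeError(ValueError):
    """Every candidate probe for a gene was degenerate."""


@dataclass
class ExpressionSampleSet:
    """Point measurements of one probe: coordinates (mm) and values."""

    sample_coords: np.ndarray  # (n_samples, 3)
    values: np.ndarray         # (n_samples,)
    probe_id: str
    gene_id: str

    def __post_init__(self):
        self.sample_coords = np.atleast_2d(np.asarray(self.sample_coords, float))
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.sample_coords.shape != (self.values.size, 3):
            raise ValueError("sample_coords must be n_samples x 3")
        if self.values.size < 1:
            raise ValueError("at least one sample is required")
        if not np.all(np.isfinite(self.sample_coords)):
            raise ValueError("sample coordinates must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.size


def kernel_regress(samples: ExpressionSampleSet, query_coords: np.ndarray,
                   sigma: float) -> np.ndarray:
    """Gaussian-kernel weighted mean of sample values at each query point.

    prediction(q) = sum_s w(q, s) v_s / sum_s w(q, s),
    w(q, s) = exp(-||q - s||^2 / (2 sigma^2)).

    Queries so distant that every weight underflows fall back to the nearest
    sample's value; the number of fallbacks is counted in a warning.
    Predictions are convex combinations of the sample values.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    query_coords = np.atleast_2d(np.asarray(query_coords, dtype=float))
    d2 = cdist(query_coords, samples.sample_coords, "sqeuclidean")
    # queries whose every unshifted weight exp(-d2/2s^2) underflows to zero
    # fall back to the nearest sample's value (float64 exp underflows ~ -745)
    dead = d2.min(axis=1) / (2.0 * sigma ** 2) > 745.0
    # subtract the row-min before exponentiating for the live queries: the
    # normalization cancels the common factor, so this is exact
    shift = d2.min(axis=1, keepdims=True)
    w = np.exp(-(d2 - shift) / (2.0 * sigma ** 2))
    pred = (w @ samples.values) / w.sum(axis=1)
    if np.any(dead):
        nearest = np.argmin(d2[dead], axis=1)
        pred[dead] = samples.values[nearest]
        warnings.warn(f"kernel_regress: {int(dead.sum())} query point(s) beyond "
                      f"kernel support; nearest-sample fallback used", stacklevel=2)
    return pred


def _loocv_accuracy(probe: ExpressionSampleSet, sigma: float) -> float:
    """Pearson correlation between observed and leave-one-out predictions."""
    n = probe.n_samples
    if n < 3 or np.std(probe.values) == 0:
        return float("-inf")
    preds = np.empty(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            rest = ExpressionSampleSet(
                np.delete(probe.sample_coords, i, axis=0),
                np.delete(probe.values, i), probe.probe_id, probe.gene_id)
            preds[i] = kernel_regress(rest, probe.sample_coords[i], sigma)[0]
    if np.std(preds) == 0:
        return float("-inf")
    return float(np.corrcoef(probe.values, preds)[0, 1])


def select_probe_loocv(probes: list[ExpressionSampleSet], sigma: float
                       ) -> tuple[ExpressionSampleSet, np.ndarray]:
    """Pick the probe whose LOOCV predictions best correlate with observation.

    Probes with fewer than 3 samples or zero value variance score -inf.
    Ties break toward the lowest probe index. Raises ``NoValidProbeError``
    when no probe attains a finite accuracy.
    """
    if not probes:
        raise ValueError("at least one probe is required")
    if len(probes) == 1:
        return probes[0], np.array([_loocv_accuracy(probes[0], sigma)])
    acc = np.array([_loocv_accuracy(p, sigma) for p in probes])
    if not np.any(np.isfinite(acc)):
        raise NoValidProbeError(
            f"all {len(probes)} probes for gene {probes[0].gene_id!r} degenerate")
    best = int(np.argmax(acc))  # argmax takes the first maximum: lowest index
    return probes[best], acc


def loocv_sigma_sweep(probes: list[ExpressionSampleSet],
                      sigmas: np.ndarray) -> pd.DataFrame:
    """LOOCV accuracy of every probe over a grid of candidate bandwidths."""
    rows = [{"sigma": float(s), "probe_id": p.probe_id,
             "accuracy": _loocv_accuracy(p, float(s))}
            for s in np.asarray(sigmas, dtype=float) for p in probes]
    return pd.DataFrame(rows)


def build_template(chosen_probes: list[ExpressionSampleSet],
                   region_assignment, region_ids: list[str],
                   region_centroids: np.ndarray | None = None,
                   sigma: float | None = None
                   ) -> tuple[GeneExpressionTemplate, list[str]]:
    """Aggregate per-region means per gene, then z-score across regions.

    ``region_assignment`` maps each sample to a region id — either one array
    shared by all probes or a dict keyed by probe_id. Regions with no sample
    for a probe are filled by kernel regression at ``region_centroids``
    (``sigma`` then required). Genes constant across regions cannot be
    z-scored; they are excluded and returned as the degenerate list.
    """
    n_regions = len(region_ids)
    pos = {r: i for i, r in enumerate(region_ids)}
    if len(pos) != n_regions:
        raise ValueError("duplicate region ids")

    rows, kept_genes, degenerate = [], [], []
    for probe in chosen_probes:
        assign = (region_assignment[probe.probe_id]
                  if isinstance(region_assignment, dict) else region_assignment)
        assign = np.asarray(assign)
        if assign.size != probe.n_samples:
            raise ValueError(f"region assignment length {assign.size} does not "
                             f"match {probe.n_samples} samples of {probe.probe_id}")
        regional = np.full(n_regions, np.nan)
        for r in range(n_regions):
            mask = assign == region_ids[r]
            if mask.any():
                regional[r] = probe.values[mask].mean()
        empty = np.isnan(regional)
        if empty.any():
            if region_centroids is None or sigma is None:
                raise ValueError(
                    f"regions without samples for {probe.probe_id}; provide "
                    f"region_centroids and sigma for interpolation")
            regional[empty] = kernel_regress(
                probe, np.asarray(region_centroids)[empty], sigma)
        if np.std(regional) == 0:
            degenerate.append(probe.gene_id)
            continue
        rows.append((regional - regional.mean()) / regional.std())
        kept_genes.append(probe.gene_id)
    matrix = np.vstack(rows) if rows else np.empty((0, n_regions))
    return GeneExpressionTemplate(matrix, kept_genes, list(region_ids)), degenerate


def read_samples_tsv(path) -> list[ExpressionSampleSet]:
    """Read point samples from TSV (probe_id, gene_id, x, y, z, value)."""
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "gene_id", "x", "y", "z", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    out = []
    for (probe, gene), grp in df.groupby(["probe_id", "gene_id"], sort=True):
        out.append(ExpressionSampleSet(
            grp[["x", "y", "z"]].to_numpy(float), grp["value"].to_numpy(float),
            str(probe), str(gene)))
    return out
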