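"""File contracts: labelled TSV matrices, HDF5 trajectories, JSON manifests.

All tabular interchange is tab-separated with full-precision scientific
formatting (lossless to parse-and-reformat round-trips); trajectories live in
one HDF5 container per cohort; every generated directory carries a JSON
manifest recording the configuration and seed that produced it.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import Connectome, GeneExpressionTemplate, SubjectTimeseries
from .synthetic import SyntheticCohort, SyntheticCohortConfig

__all__ = ["read_matrix", "write_matrix", "write_cohort", "read_cohort",
           "write_manifest", "MatrixParseError"]

_FLOAT_FMT = "%.17g"


class MatrixParseError(ValueError):
    """Malformed labelled-matrix TSV (carries the offending line number)."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


def write_matrix(path, matrix: np.ndarray, row_labels, col_labels) -> None:
    """Write a labelled matrix as TSV at full float precision."""
    df = pd.DataFrame(np.asarray(matrix, dtype=float),
                      index=list(row_labels), columns=list(col_labels))
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="id")


def read_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labelled TSV matrix; reject ragged rows and duplicate labels."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        col_labels = header[1:]
        if len(set(col_labels)) != len(col_labels):
            dup = [c for c in col_labels if col_labels.count(c) > 1][0]
            raise MatrixParseError(f"duplicate column label {dup!r}", line=1)
        rows, row_labels = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise MatrixParseError(
                    f"expected {n_cols} fields, found {len(parts)}", line=lineno)
            row_labels.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as e:
                raise MatrixParseError(str(e), line=lineno) from None
        if len(set(row_labels)) != len(row_labels):
            dup = [r for r in row_labels if row_labels.count(r) > 1][0]
            raise MatrixParseError(f"duplicate row label {dup!r}")
    return np.array(rows, dtype=float), row_labels, col_labels


def write_manifest(path, stage: str, config: dict, seed: int | None = None,
                   inputs: dict | None = None, wall_clock: float | None = None,
                   extra: dict | None = None) -> None:
    import gemcm
    manifest = {
        "stage": stage,
        "config": config,
        "seed": seed,
        "inputs": inputs or {},
        "gemcm_version": gemcm.__version__,
        "wall_clock_s": wall_clock,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Serialize a cohort: TSVs for template/connectome/cognition/coords,
    one HDF5 container for trajectories and ground truth, a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(out / "template.tsv", cohort.template.matrix,
                 cohort.template.gene_ids, cohort.template.region_ids)
    write_matrix(out / "connectome.tsv", cohort.connectome.matrix,
                 cohort.connectome.region_ids, cohort.connectome.region_ids)
    write_matrix(out / "region_coords.tsv", cohort.region_coords,
                 cohort.template.region_ids, ["x", "y", "z"])
    cohort.cognitive.to_csv(out / "cognition.tsv", sep="\t", index=False,
                            float_format=_FLOAT_FMT)
    with h5py.File(out / "trajectories.h5", "w") as h5:
        h5.attrs["factor_names"] = cohort.subjects[0].factor_names
        h5.attrs["region_ids"] = cohort.subjects[0].region_ids
        grp = h5.create_group("subjects")
        for ts in cohort.subjects:
            g = grp.create_group(ts.subject_id)
            g.create_dataset("values", data=ts.values)
            g.create_dataset("times", data=ts.times)
        truth = h5.create_group("truth")
        truth.create_dataset("gene_params", data=cohort.true_gene_params())
        truth.create_dataset("latent", data=cohort.true_latent)
        truth.create_dataset("active_indices", data=cohort.active_indices)
        truth.create_dataset("latent_indices", data=cohort.latent_indices)
        truth.create_dataset("true_slopes", data=cohort.true_slopes)
    write_manifest(out / "manifest.json", "simulate",
                   asdict(cohort.config), seed=cohort.config.seed)
    return out


def read_cohort(in_dir):
    """Load a serialized cohort directory.

    Returns ``(config, template, connectome, subjects, cognitive, truth)``
    where ``truth`` is a dict of the stored ground-truth arrays.
    """
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    config = SyntheticCohortConfig(**manifest["config"])
    tmat, gene_ids, region_ids = read_matrix(in_dir / "template.tsv")
    template = GeneExpressionTemplate(tmat, gene_ids, region_ids)
    cmat, rids, _ = read_matrix(in_dir / "connectome.tsv")
    connectome = Connectome(cmat, rids)
    cognitive = pd.read_csv(in_dir / "cognition.tsv", sep="\t")
    subjects, truth = [], {}
    with h5py.File(in_dir / "trajectories.h5", "r") as h5:
        factor_names = [str(x) for x in h5.attrs["factor_names"]]
        h5_regions = [str(x) for x in h5.attrs["region_ids"]]
        for sid in sorted(h5["subjects"]):
            g = h5["subjects"][sid]
            subjects.append(SubjectTimeseries(
                g["values"][()], g["times"][()], factor_names, h5_regions, sid))
        for key in h5["truth"]:
            truth[key] = h5["truth"][key][()]
    return config, template, connectome, subjects, cognitive, truth
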