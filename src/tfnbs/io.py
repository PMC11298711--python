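"""Plain-text serialization: matrices and datasets as CSV/TSV, models as JSON.

All node indexing in files is 0-based. Floats are written with a fixed
17-significant-digit format so that a rerun with the same seed produces
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .harmonize import CohortDataset
from .simulate import Parcellation, SyntheticCohort

__all__ = [
    "write_matrix_csv",
    "read_matrix_csv",
    "write_dataset_tsv",
    "read_dataset_tsv",
    "write_cohort",
    "read_cohort",
    "write_model_json",
    "write_json",
]

FLOAT_FMT = "%.17g"


def write_matrix_csv(matrix: np.ndarray, path) -> None:
    """n x n matrix with a node-id header row and column."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    frame = pd.DataFrame(matrix, index=range(n), columns=range(n))
    frame.to_csv(path, float_format=FLOAT_FMT, index_label="node")


def read_matrix_csv(path) -> np.ndarray:
    frame = pd.read_csv(path, index_col=0)
    return frame.to_numpy(dtype=float)


def write_dataset_tsv(dataset: CohortDataset, values_path, manifest_path=None) -> None:
    """Edge-by-subject values TSV (first two columns: node_i, node_j)."""
    cols = {"node_i": dataset.edges[:, 0], "node_j": dataset.edges[:, 1]}
    subjects = (
        dataset.covariates["subject_id"].tolist()
        if "subject_id" in dataset.covariates
        else [f"sub-{s:04d}" for s in range(dataset.n_subjects)]
    )
    for s, name in enumerate(subjects):
        cols[name] = dataset.Y[:, s]
    pd.DataFrame(cols).to_csv(values_path, sep="\t", index=False, float_format=FLOAT_FMT)
    if manifest_path is not None:
        dataset.covariates.to_csv(
            manifest_path, sep="\t", index=False, float_format=FLOAT_FMT
        )


def read_dataset_tsv(values_path, manifest_path, parcellation: Parcellation) -> CohortDataset:
    values = pd.read_csv(values_path, sep="\t")
    covariates = pd.read_csv(manifest_path, sep="\t")
    edges = values[["node_i", "node_j"]].to_numpy(dtype=int)
    Y = values.drop(columns=["node_i", "node_j"]).to_numpy(dtype=float)
    return CohortDataset(Y, edges, covariates, parcellation, log_scale=True)


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Per-subject matrix CSVs, manifest/parcellation/truth TSVs."""
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    manifest = cohort.covariates.copy()
    paths = []
    for s in range(cohort.n_subjects):
        sid = manifest["subject_id"].iloc[s]
        p = out / "matrices" / f"{sid}.csv"
        write_matrix_csv(cohort.matrices[s], p)
        paths.append(str(p.relative_to(out)))
    manifest["path"] = paths
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    cohort.parcellation.to_tsv(out / "parcellation.tsv")
    cohort.truth.rename(columns={"effect": "signed_effect"}).to_csv(
        out / "truth_edges.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    return out


def read_cohort(in_dir):
    """Read matrices + manifest + parcellation written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.tsv", sep="\t")
    parcellation = Parcellation.from_tsv(in_dir / "parcellation.tsv")
    matrices = [read_matrix_csv(in_dir / p) for p in manifest["path"]]
    covariates = manifest.drop(columns=["path"])
    return matrices, covariates, parcellation


def write_model_json(model, path) -> None:
    write_json(model.to_dict(), path)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
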