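"""File formats and run configuration.

Expression matrices are stored genes-as-rows.  Supported formats: dense
CSV/TSV (gene ids in the first column, sample ids in the header), MatrixMarket
MTX with ``genes.tsv`` / ``barcodes.tsv`` sidecars (1-based indices at the
file boundary only), and the h5ad single-cell container (where the AnnData
convention is cells x genes, transposed on the way in/out).  Assignments are
stored as sparse two-column TSV (cell_id, spot_id).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .inference import DeconvolutionResult, UncertaintyReport
from .metrics import EvaluationSummary, ProportionMatrix
from .oracle import AssignmentMatrix

_FORMATS = ("csv", "tsv", "mtx", "h5ad")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lstrip(".").lower()
    if ext not in _FORMATS:
        raise ValueError(f"cannot infer format from extension {ext!r}; "
                         f"expected one of {_FORMATS}")
    return ext


def read_expression(path: str, fmt: Optional[str] = None,
                    transpose: bool = False) -> Tuple[np.ndarray, List[str], List[str]]:
    """Read an expression matrix as (genes x columns, gene_ids, column_ids).

    ``transpose`` declares that the file stores genes as columns; it is an
    explicit override, no content-based guessing is attempted for text
    formats.  Duplicate gene ids and empty matrices are rejected.
    """
    fmt = fmt or _infer_format(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError(f"{path}: empty matrix")
        if transpose:
            df = df.T
        matrix = df.to_numpy(dtype=np.float64)
        gene_ids = [str(g) for g in df.index]
        col_ids = [str(c) for c in df.columns]
    elif fmt == "mtx":
        from scipy.io import mmread
        M = np.asarray(mmread(path).todense(), dtype=np.float64)
        if M.size == 0:
            raise ValueError(f"{path}: empty matrix")
        base = os.path.dirname(path)
        genes_path = os.path.join(base, "genes.tsv")
        barcodes_path = os.path.join(base, "barcodes.tsv")
        gene_ids = [l.strip() for l in open(genes_path) if l.strip()]
        col_ids = [l.strip() for l in open(barcodes_path) if l.strip()]
        if transpose:
            M = M.T
        matrix = M
    elif fmt == "h5ad":
        import anndata
        adata = anndata.read_h5ad(path)
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        matrix = np.asarray(X, dtype=np.float64).T  # AnnData is cells x genes
        gene_ids = [str(g) for g in adata.var_names]
        col_ids = [str(c) for c in adata.obs_names]
        if transpose:
            matrix = matrix.T
            gene_ids, col_ids = col_ids, gene_ids
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if matrix.shape[0] != len(gene_ids) or matrix.shape[1] != len(col_ids):
        raise ValueError(f"{path}: id sidecars do not match matrix shape")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError(f"{path}: duplicate gene ids")
    return matrix, gene_ids, col_ids


def write_expression(path: str, matrix: np.ndarray, gene_ids: Sequence[str],
                     col_ids: Sequence[str], fmt: Optional[str] = None) -> None:
    """Write a genes x columns matrix in any supported format."""
    fmt = fmt or _infer_format(path)
    matrix = np.asarray(matrix, dtype=np.float64)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(matrix, index=list(gene_ids),
                     columns=list(col_ids)).to_csv(path, sep=sep)
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix
        mmwrite(path, coo_matrix(matrix))
        base = os.path.dirname(path)
        with open(os.path.join(base, "genes.tsv"), "w") as fh:
            fh.write("\n".join(gene_ids) + "\n")
        with open(os.path.join(base, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(col_ids) + "\n")
    elif fmt == "h5ad":
        import anndata
        adata = anndata.AnnData(X=matrix.T)
        adata.var_names = list(gene_ids)
        adata.obs_names = list(col_ids)
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_assignment_tsv(path: str, assignment: AssignmentMatrix,
                         cell_ids: Optional[Sequence[str]] = None,
                         spot_ids: Optional[Sequence[str]] = None) -> None:
    """Sparse triplet form: one (cell_id, spot_id) line per cell."""
    spot_of = assignment.spot_index()
    cell_ids = cell_ids or [f"cell{i}" for i in range(assignment.n_cells)]
    spot_ids = spot_ids or [f"spot{j}" for j in range(assignment.n_spots)]
    with open(path, "w") as fh:
        fh.write("cell_id\tspot_id\n")
        for i, j in enumerate(spot_of):
            fh.write(f"{cell_ids[i]}\t{spot_ids[j]}\n")


def read_assignment_tsv(path: str, n_cells: int, n_spots: int,
                        cell_ids: Sequence[str],
                        spot_ids: Sequence[str]) -> AssignmentMatrix:
    df = pd.read_csv(path, sep="\t")
    cpos = {c: i for i, c in enumerate(cell_ids)}
    spos = {s: j for j, s in enumerate(spot_ids)}
    entries = np.zeros((n_cells, n_spots))
    for _, row in df.iterrows():
        entries[cpos[str(row["cell_id"])], spos[str(row["spot_id"])]] = 1.0
    return AssignmentMatrix(entries)


def write_proportions_csv(path: str, props: ProportionMatrix,
                          spot_ids: Optional[Sequence[str]] = None,
                          type_names: Optional[Sequence[str]] = None) -> None:
    spot_ids = spot_ids or [f"spot{j}" for j in range(props.n_spots)]
    type_names = type_names or [f"type{k}" for k in range(props.n_types)]
    pd.DataFrame(props.values, index=list(spot_ids),
                 columns=list(type_names)).to_csv(path)


def read_proportions_csv(path: str) -> Tuple[np.ndarray, List[str], List[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=np.float64), list(df.index), list(df.columns)


@dataclass
class RunConfig:
    """Serializable bundle of command parameters plus the global seed."""

    command: str
    params: Dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."
    verbosity: int = 1

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            if path.endswith((".yaml", ".yml")):
                yaml.safe_dump(self.to_dict(), fh)
            else:
                json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) \
                else json.load(fh)
        return cls(**obj)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def write_results(result, out_dir: str, config: Optional[RunConfig] = None,
                  type_names: Optional[Sequence[str]] = None,
                  schedule_json: Optional[str] = None,
                  checkpoint_id: Optional[str] = None) -> List[str]:
    """Write a result object to a directory; returns the files written.

    Handles :class:`DeconvolutionResult`, :class:`UncertaintyReport` and
    :class:`EvaluationSummary`.  A ``metadata.json`` with the config hash,
    seed and schedule summary is always produced.
    """
    os.makedirs(out_dir, exist_ok=True)
    written: List[str] = []

    def _path(name: str) -> str:
        p = os.path.join(out_dir, name)
        written.append(p)
        return p

    if isinstance(result, DeconvolutionResult):
        write_proportions_csv(_path("proportions.csv"), result.proportions,
                              type_names=type_names)
        write_assignment_tsv(_path("assignment.tsv"), result.assignment)
        pd.DataFrame({"cosine": result.per_spot_cosine}).to_csv(
            _path("per_spot_cosine.csv"))
        if result.trajectory is not None:
            frames = [{"t": f.t,
                       "mean_cosine": float(np.mean(f.per_spot_cosine))}
                      for f in result.trajectory]
            with open(_path("trajectory.json"), "w") as fh:
                json.dump(frames, fh, indent=2)
    elif isinstance(result, UncertaintyReport):
        n_s, n_t = result.mean.shape
        names = type_names or [f"type{k}" for k in range(n_t)]
        rows = []
        for i in range(n_s):
            for k in range(n_t):
                rows.append({"spot": f"spot{i}", "type": names[k],
                             "mean": result.mean[i, k],
                             "std": result.std[i, k],
                             "ci_lower": result.ci_lower[i, k],
                             "ci_upper": result.ci_upper[i, k]})
        pd.DataFrame(rows).to_csv(_path("uncertainty.csv"), index=False)
    elif isinstance(result, EvaluationSummary):
        with open(_path("summary.json"), "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
    else:
        raise TypeError(f"cannot write result of type {type(result).__name__}")

    meta = {"schema_version": 1,
            "seed": config.seed if config else None,
            "config_hash": config.digest() if config else None,
            "schedule": json.loads(schedule_json) if schedule_json else None,
            "checkpoint_id": checkpoint_id}
    with open(_path("metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    return written
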