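"""Data model and I/O for spatially resolved transcriptomics (SRT) slices.

A slice is a tuple of an ``n x p`` spot-by-feature expression matrix and an
``n x 2`` matrix of planar spot coordinates, optionally with per-spot
cell-type labels and a timepoint tag.  Alignments between two slices are
``n1 x n2`` coupling matrices together with the per-spot growth vector they
induce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Slice",
    "AlignmentResult",
    "load_slice",
    "preprocess",
    "save_alignment",
    "load_alignment",
]


@dataclass(frozen=True)
class Slice:
    """One timepoint's expression matrix, spot coordinates and metadata.

    Parameters
    ----------
    expression
        ``(n, p)`` non-negative expression matrix (counts or normalized).
    coords
        ``(n, 2)`` planar spot positions, arbitrary length units.
    spot_ids
        ``n`` unique spot identifiers; defaults to ``s0..s{n-1}``.
    labels
        Optional ``n`` categorical cell-type labels.
    timepoint
        Optional real-valued time tag.
    """

    expression: np.ndarray
    coords: np.ndarray
    spot_ids: tuple[str, ...] = ()
    labels: Optional[tuple[str, ...]] = None
    timepoint: Optional[float] = None

    def __post_init__(self) -> None:
        X = np.asarray(self.expression, dtype=float)
        S = np.asarray(self.coords, dtype=float)
        if X.ndim != 2 or S.ndim != 2:
            raise ValueError("expression and coords must be 2-D arrays")
        if S.shape[1] != 2:
            raise ValueError("coords must be n×2")
        if X.shape[0] != S.shape[0]:
            raise ValueError(
                f"row-count mismatch: expression has {X.shape[0]} rows, "
                f"coords has {S.shape[0]}"
            )
        if X.shape[0] < 2:
            raise ValueError("a slice needs at least 2 spots")
        for name, A in (("expression", X), ("coords", S)):
            bad = ~np.isfinite(A)
            if bad.any():
                row = int(np.argwhere(bad)[0, 0])
                raise ValueError(f"non-finite value in {name} at row {row}")
        object.__setattr__(self, "expression", X)
        object.__setattr__(self, "coords", S)
        ids = tuple(self.spot_ids) or tuple(f"s{i}" for i in range(X.shape[0]))
        if len(ids) != X.shape[0]:
            raise ValueError("spot_ids length does not match spot count")
        object.__setattr__(self, "spot_ids", ids)
        if self.labels is not None:
            lab = tuple(str(x) for x in self.labels)
            if len(lab) != X.shape[0]:
                raise ValueError("labels length does not match spot count")
            object.__setattr__(self, "labels", lab)

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_features(self) -> int:
        return self.expression.shape[1]


@dataclass
class AlignmentResult:
    """Output of a slice-pair alignment.

    ``pi`` is the non-negative coupling whose columns each carry mass
    ``1/n1`` (total mass ``n2/n1``); ``xi = pi @ 1 - 1/n1`` is the per-spot
    mass flux; ``duals`` are the row/column log-domain potentials of the
    inner solver; ``objective_trace`` records the objective at each outer
    iteration; ``params`` echoes the resolved hyperparameters.
    """

    pi: np.ndarray
    xi: np.ndarray
    duals: tuple[np.ndarray, np.ndarray]
    objective_trace: list[float] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    def validate(self, tol: float = 1e-6) -> None:
        n1, n2 = self.pi.shape
        if (self.pi < 0).any():
            raise ValueError("pi has negative entries")
        col = self.pi.sum(axis=0)
        if np.abs(col - 1.0 / n1).max() > tol:
            raise ValueError("pi columns do not sum to 1/n1")
        if abs(self.xi.sum() - (n2 - n1) / n1) > tol:
            raise ValueError("xi does not sum to (n2-n1)/n1")


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def load_slice(path, format: str = "h5ad", *, coords_path=None,
               timepoint: Optional[float] = None) -> Slice:
    """Read a slice from disk.

    ``format="h5ad"`` reads an AnnData file with spot coordinates under
    ``obsm["spatial"]`` and optional labels in ``obs["cell_type"]``.
    ``format="csv_pair"`` reads an expression table at ``path`` and a
    coordinates table at ``coords_path``; both have a header row, a
    spot-identifier first column, and matching row identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        if "spatial" not in adata.obsm:
            raise ValueError("h5ad file has no obsm['spatial'] coordinates")
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        labels = None
        if "cell_type" in adata.obs:
            labels = tuple(str(x) for x in adata.obs["cell_type"])
        return Slice(
            expression=np.asarray(X, dtype=float),
            coords=np.asarray(adata.obsm["spatial"], dtype=float),
            spot_ids=tuple(str(x) for x in adata.obs_names),
            labels=labels,
            timepoint=timepoint,
        )
    if format == "csv_pair":
        if coords_path is None:
            raise ValueError("csv_pair format requires coords_path")
        expr = _read_table(path)
        coords = _read_table(Path(coords_path))
        if coords.shape[1] != 2:
            raise ValueError("coords must be n×2")
        if list(expr.index) != list(coords.index):
            raise ValueError("expression and coordinates row identifiers differ")
        return Slice(
            expression=expr.to_numpy(dtype=float),
            coords=coords.to_numpy(dtype=float),
            spot_ids=tuple(str(x) for x in expr.index),
            timepoint=timepoint,
        )
    raise ValueError(f"unknown format {format!r}")


def preprocess(sl: Slice, normalize: bool = True, log1p: bool = True,
               target_sum: float = 1.0) -> Slice:
    """Library-size normalize rows to ``target_sum`` and/or apply log(1+x).

    Coordinates, identifiers and labels pass through unchanged.  Rows that
    are entirely zero are rejected: expression distances to such spots are
    undefined downstream.
    """
    X = np.asarray(sl.expression, dtype=float)
    if (X < 0).any():
        raise ValueError("expression must be non-negative")
    if normalize:
        totals = X.sum(axis=1)
        zero = np.nonzero(totals == 0)[0]
        if zero.size:
            raise ValueError(f"all-zero expression row {int(zero[0])}")
        X = X * (target_sum / totals)[:, None]
    if log1p:
        X = np.log1p(X)
    return replace(sl, expression=X)


def save_alignment(result: AlignmentResult, path, format: str = "dense_csv",
                   row_ids: Optional[Sequence[str]] = None,
                   col_ids: Optional[Sequence[str]] = None) -> None:
    """Write an alignment to ``path`` (a directory).

    The coupling goes to ``pi.csv`` (dense, row/column identifiers) or
    ``pi_triplets.tsv`` (``row_id  col_id  value`` for nonzero entries);
    the growth vector to ``xi.csv``; the hyperparameters to ``params.json``.
    """
    result.validate(tol=1e-6)
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    n1, n2 = result.pi.shape
    rows = list(row_ids) if row_ids is not None else [f"s{i}" for i in range(n1)]
    cols = list(col_ids) if col_ids is not None else [f"t{j}" for j in range(n2)]
    if format == "dense_csv":
        pd.DataFrame(result.pi, index=rows, columns=cols).to_csv(
            out / "pi.csv", float_format="%.17g")
    elif format == "sparse_triplets":
        i, j = np.nonzero(result.pi)
        df = pd.DataFrame({
            "row_id": [rows[k] for k in i],
            "col_id": [cols[k] for k in j],
            "value": result.pi[i, j],
        })
        df.to_csv(out / "pi_triplets.tsv", sep="\t", index=False,
                  float_format="%.17g")
    else:
        raise ValueError(f"unknown format {format!r}")
    pd.DataFrame({"spot_id": rows, "xi": result.xi}).to_csv(
        out / "xi.csv", index=False, float_format="%.17g")
    with open(out / "params.json", "w") as fh:
        json.dump(result.params, fh, indent=2, default=str)


def load_alignment(path, format: str = "dense_csv") -> AlignmentResult:
    """Read back an alignment written by :func:`save_alignment`."""
    out = Path(path)
    xi_df = pd.read_csv(out / "xi.csv", float_precision="round_trip")
    xi = xi_df["xi"].to_numpy(dtype=float)
    if format == "dense_csv":
        pi_df = pd.read_csv(out / "pi.csv", index_col=0,
                            float_precision="round_trip")
        pi = pi_df.to_numpy(dtype=float)
    elif format == "sparse_triplets":
        tri = pd.read_csv(out / "pi_triplets.tsv", sep="\t",
                          float_precision="round_trip")
        rows = list(dict.fromkeys(xi_df["spot_id"]))
        cols = list(dict.fromkeys(tri["col_id"]))
        ri = {r: k for k, r in enumerate(rows)}
        ci = {c: k for k, c in enumerate(cols)}
        pi = np.zeros((len(rows), len(cols)))
        for r, c, v in zip(tri["row_id"], tri["col_id"], tri["value"]):
            pi[ri[r], ci[c]] = v
    else:
        raise ValueError(f"unknown format {format!r}")
    params = {}
    pfile = out / "params.json"
    if pfile.exists():
        params = json.loads(pfile.read_text())
    n1 = pi.shape[0]
    return AlignmentResult(pi=pi, xi=xi,
                           duals=(np.zeros(n1), np.zeros(pi.shape[1])),
                           params=params)
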