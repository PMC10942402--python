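"""Cost matrices for slice alignment.

Builds the inter-slice expression distance matrix ``C``, intra-slice
expression distances ``C1``/``C2``, intra-slice spatial distances
``D1``/``D2``, and the merged feature-spatial matrices ``M1``/``M2`` — the
entrywise products ``Ci ∘ Di`` that let the higher-order objective terms
match a feature-smoothed geometry instead of a rigid spatial one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .slices import Slice

__all__ = [
    "CostBundle",
    "expression_distance",
    "spatial_distance",
    "merged_matrix",
    "build_costs",
]

_KL_SMOOTH = 1e-10


@dataclass(frozen=True)
class CostBundle:
    """Distance matrices shared by the objective and solver.

    ``C`` is ``n1 x n2`` inter-slice expression distance; ``M1``/``M2`` are
    the symmetric zero-diagonal merged feature-spatial matrices of each
    slice.  ``metric_name`` and ``normalization_name`` record how they were
    built.
    """

    C: np.ndarray
    M1: np.ndarray
    M2: np.ndarray
    metric_name: str = "euclidean"
    normalization_name: str = "unit_mean"

    def __post_init__(self) -> None:
        for name, M in (("M1", self.M1), ("M2", self.M2)):
            if M.shape[0] != M.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(M, M.T, atol=1e-8):
                raise ValueError(f"{name} must be symmetric")
        for name, A in (("C", self.C), ("M1", self.M1), ("M2", self.M2)):
            if not np.isfinite(A).all():
                raise ValueError(f"non-finite entries in {name}")
            if (A < 0).any():
                raise ValueError(f"negative entries in {name}")


def expression_distance(X_a: np.ndarray, X_b: np.ndarray,
                        metric: str = "euclidean",
                        smooth: bool = True) -> np.ndarray:
    """Pairwise expression distance between the rows of two matrices.

    Supported metrics: ``euclidean``, ``cosine`` (1 − cosine similarity)
    and ``kl`` (symmetrized KL divergence of row-normalized profiles, with
    additive smoothing unless ``smooth=False``).
    """
    X_a = np.asarray(X_a, dtype=float)
    X_b = np.asarray(X_b, dtype=float)
    if X_a.shape[1] != X_b.shape[1]:
        raise ValueError(
            f"feature count mismatch: {X_a.shape[1]} vs {X_b.shape[1]}")
    if metric in ("euclidean", "cosine"):
        D = cdist(X_a, X_b, metric=metric)
        return np.maximum(D, 0.0)
    if metric == "kl":
        if smooth:
            X_a = X_a + _KL_SMOOTH
            X_b = X_b + _KL_SMOOTH
        if (X_a <= 0).any() or (X_b <= 0).any():
            raise ValueError("kl metric requires strictly positive rows "
                             "(enable smoothing)")
        P = X_a / X_a.sum(axis=1, keepdims=True)
        Q = X_b / X_b.sum(axis=1, keepdims=True)
        logP, logQ = np.log(P), np.log(Q)
        # symmetrized KL: sum_k (p-q) (log p - log q), expanded to avoid loops
        cross = P @ logQ.T + logP @ Q.T
        self_ = (P * logP).sum(1)[:, None] + (Q * logQ).sum(1)[None, :]
        return np.maximum(self_ - cross, 0.0)
    raise ValueError(f"unknown metric {metric!r}")


def spatial_distance(S: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix of one slice's coordinates."""
    S = np.asarray(S, dtype=float)
    if not np.isfinite(S).all():
        raise ValueError("non-finite coordinates")
    D = cdist(S, S)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2


def _normalize(A: np.ndarray, normalization: str) -> np.ndarray:
    """Scale a distance matrix so its magnitude is unit-free.

    ``unit_mean`` divides by the mean off-diagonal entry (square matrices)
    or the overall mean (rectangular); ``unit_max`` divides by the maximum;
    ``none`` passes through.
    """
    if normalization == "none":
        return A
    if normalization == "unit_mean":
        if A.shape[0] == A.shape[1]:
            n = A.shape[0]
            off = A.sum() - np.trace(A)
            denom = off / (n * (n - 1)) if n > 1 else 0.0
        else:
            denom = A.mean()
    elif normalization == "unit_max":
        denom = A.max()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if denom == 0:
        raise ValueError("cannot normalize an all-zero matrix")
    return A / denom


def merged_matrix(C_intra: np.ndarray, D_intra: np.ndarray,
                  normalization: str = "unit_mean") -> np.ndarray:
    """Entrywise product of intra-slice expression and spatial distances.

    Both factors are rescaled first (default: unit off-diagonal mean) so the
    product is independent of coordinate units and expression scale.
    """
    C_intra = np.asarray(C_intra, dtype=float)
    D_intra = np.asarray(D_intra, dtype=float)
    if C_intra.shape != D_intra.shape:
        raise ValueError("size mismatch between expression and spatial matrices")
    for name, A in (("expression", C_intra), ("spatial", D_intra)):
        if not np.allclose(A, A.T, atol=1e-8):
            raise ValueError(f"intra-slice {name} matrix must be symmetric")
    M = _normalize(C_intra, normalization) * _normalize(D_intra, normalization)
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    return M


def build_costs(slice1: Slice, slice2: Slice, metric: str = "euclidean",
                normalization: str = "unit_mean") -> CostBundle:
    """Assemble the full cost bundle for a slice pair.

    The same normalization convention is applied to the inter-slice ``C`` so
    that the doublet and merged terms are on comparable scales.
    """
    if slice1.n_features != slice2.n_features:
        raise ValueError(
            f"feature count mismatch: {slice1.n_features} vs "
            f"{slice2.n_features}")
    C = expression_distance(slice1.expression, slice2.expression, metric)
    if normalization != "none" and C.max() > 0:
        C = _normalize(C, normalization)
    M1 = merged_matrix(
        expression_distance(slice1.expression, slice1.expression, metric),
        spatial_distance(slice1.coords), normalization)
    M2 = merged_matrix(
        expression_distance(slice2.expression, slice2.expression, metric),
        spatial_distance(slice2.coords), normalization)
    return CostBundle(C=C, M1=M1, M2=M2, metric_name=metric,
                      normalization_name=normalization)
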