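"""Alignment-quality metrics: growth distortion and migration.

Growth distortion compares the inferred per-spot growth vector against the
"true" per-type growth implied by cell-type counts at the two timepoints,
optionally minimized over reverse-time cell-type transition matrices.
Migration measures the mean squared displacement between first-slice spots
and rigidly registered second-slice spots, weighted by the coupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .growth import GrowthVector

__all__ = [
    "CellTypePartition",
    "TransitionMatrix",
    "true_growth",
    "growth_distortion",
    "transition_matrix",
    "growth_distortion_with_transitions",
    "procrustes",
    "migration_metric",
    "transition_graph",
]


@dataclass(frozen=True)
class CellTypePartition:
    """Assignment of spots to cell types with per-type spot counts."""

    labels: tuple[str, ...]
    types: tuple[str, ...]

    @classmethod
    def from_labels(cls, labels: Sequence[str],
                    types: Optional[Sequence[str]] = None
                    ) -> "CellTypePartition":
        labels = tuple(str(x) for x in labels)
        if types is None:
            types = tuple(dict.fromkeys(labels))  # first-appearance order
        else:
            types = tuple(types)
            missing = set(labels) - set(types)
            if missing:
                raise ValueError(f"labels not in type list: {sorted(missing)}")
        return cls(labels=labels, types=types)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def masses(self) -> np.ndarray:
        """Per-type spot counts, ordered as ``types``."""
        return np.array([sum(l == t for l in self.labels)
                         for t in self.types], dtype=float)

    def indices(self, t: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == t],
                        dtype=int)


@dataclass(frozen=True)
class TransitionMatrix:
    """Reverse-time cell-type transition matrix.

    Entry ``(p, q)`` is the fraction of type-``q`` mass at the later
    timepoint ascribed to type-``p`` ancestors at the earlier timepoint;
    columns sum to 1 whenever the coupling is column-feasible.
    """

    T: np.ndarray
    row_types: tuple[str, ...]
    col_types: tuple[str, ...]


def _shared_types(p1: CellTypePartition, p2: CellTypePartition
                  ) -> tuple[str, ...]:
    """Union of the two type universes, t1-first-appearance order."""
    return tuple(dict.fromkeys(list(p1.types) + list(p2.types)))


def true_growth(p1: CellTypePartition, p2: CellTypePartition
                ) -> dict[str, float]:
    """Per-type growth under the no-transition, equal-share assumptions.

    For each type present at t1, gamma_p = (m2p - m1p) / (m1p * n1): the
    normalized change in that type's mass shared equally across its t1
    spots.  Types new at t2 (m1p = 0) are excluded; callers needing them
    must go through the transition-matrix variant.  The masses satisfy
    sum_p m1p * gamma_p = (n2 - n1)/n1.
    """
    n1 = p1.n
    types = _shared_types(p1, p2)
    m1 = {t: sum(l == t for l in p1.labels) for t in types}
    m2 = {t: sum(l == t for l in p2.labels) for t in types}
    return {t: (m2[t] - m1[t]) / (m1[t] * n1)
            for t in types if m1[t] > 0}


def growth_distortion(gv: GrowthVector, p1: CellTypePartition,
                      p2: CellTypePartition) -> float:
    """Sum of squared deviations of xi from the per-type true growth.

    Defined only when no type is new at t2; new types make the
    no-transition target undefined and the caller is directed to
    :func:`growth_distortion_with_transitions`.
    """
    if gv.xi.shape[0] != p1.n:
        raise ValueError("growth vector length does not match partition")
    new_types = [t for t in p2.types
                 if t not in set(p1.labels) and any(l == t for l in p2.labels)]
    if new_types:
        raise ValueError(
            f"types new at t2 ({new_types}): use "
            "growth_distortion_with_transitions")
    gamma = true_growth(p1, p2)
    total = 0.0
    for t, g in gamma.items():
        idx = p1.indices(t)
        total += float(((gv.xi[idx] - g) ** 2).sum())
    return total


def transition_matrix(Pi: np.ndarray, p1: CellTypePartition,
                      p2: CellTypePartition, *, warn=None
                      ) -> TransitionMatrix:
    """Reverse-time transition matrix induced by a coupling.

    T_pq = (n1 / m2q) * sum_{i in type p at t1} sum_{j' in type q at t2}
    Pi_ij'.  Types empty at t2 are dropped (their column is undefined).
    """
    Pi = np.asarray(Pi, dtype=float)
    n1 = Pi.shape[0]
    if p1.n != n1 or p2.n != Pi.shape[1]:
        raise ValueError("partition sizes do not match coupling shape")
    col_types = [t for t in p2.types if any(l == t for l in p2.labels)]
    row_types = list(p1.types)
    T = np.zeros((len(row_types), len(col_types)))
    for qi, q in enumerate(col_types):
        jdx = p2.indices(q)
        m2q = len(jdx)
        for pi_, p in enumerate(row_types):
            idx = p1.indices(p)
            T[pi_, qi] = (n1 / m2q) * Pi[np.ix_(idx, jdx)].sum()
    return TransitionMatrix(T=T, row_types=tuple(row_types),
                            col_types=tuple(col_types))


def growth_distortion_with_transitions(
        gv: GrowthVector, Pi: np.ndarray, p1: CellTypePartition,
        p2: CellTypePartition) -> tuple[float, TransitionMatrix]:
    """Minimum growth distortion over cell-type transitions.

    The coupling-induced transition matrix redistributes the later
    timepoint's per-type mass onto ancestral types; the resulting per-type
    growth target gamma_p(T) = ((T m2)_p - m1p)/(m1p n1) equals the mean of
    xi over type p's t1 spots, so the metric reduces to the within-type sum
    of squared deviations of xi.  This is the minimum achievable under any
    column-stochastic transition matrix.
    """
    tm = transition_matrix(Pi, p1, p2)
    m2 = np.array([sum(l == t for l in p2.labels) for t in tm.col_types],
                  dtype=float)
    m1 = np.array([sum(l == t for l in p1.labels) for t in tm.row_types],
                  dtype=float)
    n1 = p1.n
    redistributed = tm.T @ m2
    total = 0.0
    for pi_, p in enumerate(tm.row_types):
        idx = p1.indices(p)
        if idx.size == 0:
            continue
        gamma_p = (redistributed[pi_] - m1[pi_]) / (m1[pi_] * n1)
        total += float(((gv.xi[idx] - gamma_p) ** 2).sum())
    return total, tm


def procrustes(S1: np.ndarray, S2: np.ndarray, Pi: np.ndarray,
               allow_reflection: bool = True
               ) -> tuple[np.ndarray, np.ndarray]:
    """Coupling-weighted rigid registration of slice 2 onto slice 1.

    Finds the orthogonal ``Q`` (reflections allowed unless disabled) and
    translation ``h`` minimizing ``sum_ij Pi_ij ||s_i - (Q s'_j - h)||^2``;
    the mapped position of a second-slice point ``z`` is ``Q z - h``.
    Computed by weighted centering and the SVD of the weighted
    cross-covariance.
    """
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    Pi = np.asarray(Pi, dtype=float)
    W = Pi.sum()
    if W <= 0:
        raise ValueError("coupling must have positive total mass")
    r = Pi.sum(axis=1)
    c = Pi.sum(axis=0)
    mu1 = (r @ S1) / W
    mu2 = (c @ S2) / W
    A = (S1 - mu1).T @ Pi @ (S2 - mu2)
    U, sv, Vt = np.linalg.svd(A)
    if sv[-1] < 1e-12 * max(1.0, sv[0]):
        import warnings as _w
        _w.warn("rank-deficient cross-covariance (collinear points); "
                "registration not unique", stacklevel=2)
    Q = U @ Vt
    if not allow_reflection and np.linalg.det(Q) < 0:
        D = np.diag([1.0, -1.0])
        Q = U @ D @ Vt
    h = Q @ mu2 - mu1
    return Q, h


def migration_metric(S1: np.ndarray, S2: np.ndarray, Pi: np.ndarray,
                     transform: Optional[tuple[np.ndarray, np.ndarray]] = None
                     ) -> float:
    """Mean squared ancestor-descendant displacement under the coupling.

    Columns of ``Pi`` are normalized to conditional ancestor distributions
    and averaged with uniform weight 1/n2:
    (1/n2) sum_j' sum_i (Pi_ij'/c_j') ||s_i - phi(s'_j')||^2, with phi the
    Procrustes rigid map when no transform is given.  Zero columns are
    skipped.
    """
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    Pi = np.asarray(Pi, dtype=float)
    if transform is None:
        transform = procrustes(S1, S2, Pi)
    Q, h = transform
    S2m = S2 @ Q.T - h
    c = Pi.sum(axis=0)
    nz = c > 0
    if not nz.all():
        import warnings as _w
        _w.warn(f"{int((~nz).sum())} zero columns skipped", stacklevel=2)
    n2 = Pi.shape[1]
    # squared distances between every s_i and every mapped s'_j
    D2 = ((S1[:, None, :] - S2m[None, :, :]) ** 2).sum(axis=2)
    contrib = (Pi[:, nz] / c[nz]) * D2[:, nz]
    return float(contrib.sum()) / n2


def transition_graph(tm: TransitionMatrix, threshold: float = 0.20
                     ) -> list[tuple[str, str, float]]:
    """Frequent-transition edge list from a transition matrix.

    Returns directed edges ``(ancestor_type, descendant_type, weight)`` for
    every entry above the threshold, self-loops omitted.
    """
    edges = []
    for pi_, p in enumerate(tm.row_types):
        for qi, q in enumerate(tm.col_types):
            if p != q and tm.T[pi_, qi] > threshold:
                edges.append((p, q, float(tm.T[pi_, qi])))
    return edges
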