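"""Alignment objective: doublet, triplet and quartet terms and the gradient.

The objective combines a linear feature term (the *doublet*: expression
distance between one spot from each slice) with a quadratic merged
feature-spatial term.  The merged term is the sum of a *triplet* term — one
ancestor with two descendants, or two ancestors with one descendant, whose
pairwise merged distance should be small — and a *quartet* term — the
Gromov-Wasserstein-style comparison of a spot pair in each slice under the
merged geometry:

    E(Pi) = (1-alpha) * <C, Pi> + alpha * (triplet + quartet).

All quadratic quantities are evaluated through matrix identities (never the
explicit O(n^4) tensor); the row marginal ``r = Pi @ 1`` is free under the
semi-relaxed constraint, so the ``r``-dependent quartet pieces are kept in
the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .costs import CostBundle

__all__ = [
    "ObjectiveValue",
    "doublet_term",
    "triplet_term",
    "quartet_term",
    "merged_gradient",
    "total_objective",
]


@dataclass(frozen=True)
class ObjectiveValue:
    doublet: float
    triplet: float
    quartet: float
    alpha: float

    @property
    def merged(self) -> float:
        return self.triplet + self.quartet

    @property
    def total(self) -> float:
        return (1.0 - self.alpha) * self.doublet + self.alpha * self.merged


def _check_sym(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError(f"{name} must be square symmetric")
    return M


def doublet_term(C: np.ndarray, Pi: np.ndarray) -> float:
    """Entrywise inner product <C, Pi>."""
    C = np.asarray(C, dtype=float)
    Pi = np.asarray(Pi, dtype=float)
    if C.shape != Pi.shape:
        raise ValueError(f"shape mismatch: C {C.shape} vs Pi {Pi.shape}")
    return float((C * Pi).sum())


def triplet_term(M1: np.ndarray, M2: np.ndarray, Pi: np.ndarray) -> float:
    """Half-sum of descendant-pair and ancestor-pair penalties.

    (1/2) [ sum_{i,j',k'} Pi_ij' Pi_ik' M2_j'k'^2
          + sum_{i,j,k'}  Pi_ik' Pi_jk' M1_ij^2 ]
    = (1/2) [ <Pi, Pi (M2∘M2)> + <Pi, (M1∘M1) Pi> ].
    """
    M1 = _check_sym(M1, "M1")
    M2 = _check_sym(M2, "M2")
    Pi = np.asarray(Pi, dtype=float)
    M1sq = M1 * M1
    M2sq = M2 * M2
    return 0.5 * float((Pi * (Pi @ M2sq)).sum() + (Pi * (M1sq @ Pi)).sum())


def quartet_term(M1: np.ndarray, M2: np.ndarray, Pi: np.ndarray) -> float:
    """sum_{i,j',k,l'} (M1_ik − M2_j'l')^2 Pi_ij' Pi_kl'.

    Evaluated by the square expansion <(M1∘M1) r, r> + <(M2∘M2) c, c>
    − 2 <M1 Pi M2, Pi> with r = Pi@1 and c = Pi.T@1.
    """
    M1 = _check_sym(M1, "M1")
    M2 = _check_sym(M2, "M2")
    Pi = np.asarray(Pi, dtype=float)
    r = Pi.sum(axis=1)
    c = Pi.sum(axis=0)
    M1sq = M1 * M1
    M2sq = M2 * M2
    val = (float(r @ (M1sq @ r)) + float(c @ (M2sq @ c))
           - 2.0 * float((Pi * (M1 @ Pi @ M2)).sum()))
    return val


def merged_gradient(M1: np.ndarray, M2: np.ndarray, Pi: np.ndarray
                    ) -> np.ndarray:
    """Gradient of triplet + quartet with respect to Pi.

    Triplet part: (M1∘M1) Pi + Pi (M2∘M2).
    Quartet part: 2 [ (M1∘M1) r 1^T + 1 ((M2∘M2) c)^T − 2 M1 Pi M2 ],
    with r = Pi@1, c = Pi.T@1.  The r-dependent term is retained because the
    row marginal is not fixed under semi-relaxation.
    """
    M1 = _check_sym(M1, "M1")
    M2 = _check_sym(M2, "M2")
    Pi = np.asarray(Pi, dtype=float)
    if Pi.shape != (M1.shape[0], M2.shape[0]):
        raise ValueError("Pi shape incompatible with M1/M2")
    r = Pi.sum(axis=1)
    c = Pi.sum(axis=0)
    M1sq = M1 * M1
    M2sq = M2 * M2
    grad_triplet = M1sq @ Pi + Pi @ M2sq
    grad_quartet = 2.0 * ((M1sq @ r)[:, None] + (M2sq @ c)[None, :]
                          - 2.0 * (M1 @ Pi @ M2))
    return grad_triplet + grad_quartet


def total_objective(bundle: CostBundle, Pi: np.ndarray, alpha: float
                    ) -> ObjectiveValue:
    """Evaluate all objective components for a coupling.

    ``alpha=0`` reduces to the expression-only (doublet) objective,
    ``alpha=1`` to the merged feature-spatial term alone.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return ObjectiveValue(
        doublet=doublet_term(bundle.C, Pi),
        triplet=triplet_term(bundle.M1, bundle.M2, Pi),
        quartet=quartet_term(bundle.M1, bundle.M2, Pi),
        alpha=float(alpha),
    )
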