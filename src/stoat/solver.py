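"""Semi-relaxed entropic solver for spatiotemporal slice alignment.

The optimization is

    min_{Pi >= 0, Pi^T 1 = g2}  E(Pi) + gamma * KL(Pi 1 || g1) - eps * H(Pi)

where ``E`` is the doublet + merged objective, ``g1`` is the uniform
probability measure 1/n1 over the first slice's spots and ``g2`` assigns the
same weight 1/n1 to every second-slice spot (total mass n2/n1).  The column
constraint is hard — every descendant spot must be fully explained — while
the row marginal is only KL-penalized, so ancestor spots are free to grow
(row mass > 1/n1) or die (row mass < 1/n1).

The outer loop linearizes the quadratic merged term at the current iterate
and hands the linearized cost to an inner log-domain Sinkhorn whose row
update is damped by gamma/(gamma + eps) (the KL prox) and whose column
update is exact (the hard constraint).  Dual potentials are warm-started
across outer iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .costs import CostBundle, build_costs
from .objective import merged_gradient, total_objective
from .slices import AlignmentResult, Slice

__all__ = ["SolverConfig", "semirelaxed_sinkhorn", "align"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverConfig:
    """Hyperparameters of the alignment solver.

    alpha
        Balance between the expression (doublet) term and the merged
        feature-spatial term, in [0, 1].
    gamma
        Strength of the KL penalty tying the row marginal to g1; large
        gamma approaches balanced transport.
    epsilon
        Entropic regularization strength, on unit-mean-normalized costs.
    """

    alpha: float = 0.5
    gamma: float = 0.1
    epsilon: float = 1e-2
    inner_tol: float = 1e-8
    outer_tol: float = 1e-7
    max_inner: int = 2000
    max_outer: int = 200
    metric: str = "euclidean"
    normalization: str = "unit_mean"
    seed: int = 0  # reserved; the solver is deterministic

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.gamma <= 0 or self.epsilon <= 0:
            raise ValueError("gamma and epsilon must be > 0")
        if self.inner_tol <= 0 or self.outer_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.max_inner < 1 or self.max_outer < 1:
            raise ValueError("iteration caps must be >= 1")


def semirelaxed_sinkhorn(G: np.ndarray, g1: np.ndarray, g2: np.ndarray,
                         gamma: float, epsilon: float,
                         inner_tol: float = 1e-8, max_inner: int = 2000,
                         f0: Optional[np.ndarray] = None,
                         h0: Optional[np.ndarray] = None,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Solve the linear semi-relaxed entropic problem in the log domain.

    Minimizes ``<G, Pi> + gamma*KL(Pi@1 || g1) - eps*H(Pi)`` subject to
    ``Pi.T@1 = g2``, ``Pi >= 0``.  The optimal coupling has the Gibbs form
    ``Pi_ij = exp((f_i + h_j - G_ij)/eps)``; the row potential ``f`` is the
    KL-prox fixed point (damping exponent ``gamma/(gamma+eps)``) and the
    column potential ``h`` enforces the marginal exactly.  Returns
    ``(Pi, f, h, converged)``; the last column update is applied after the
    stopping test, so the returned coupling is column-feasible to machine
    precision.
    """
    G = np.asarray(G, dtype=float)
    if not np.isfinite(G).all():
        raise ValueError("non-finite entries in cost matrix")
    n1, n2 = G.shape
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    log_g1 = np.log(g1)
    log_g2 = np.log(g2)
    f = np.zeros(n1) if f0 is None else np.array(f0, dtype=float)
    h = np.zeros(n2) if h0 is None else np.array(h0, dtype=float)
    damp = gamma / (gamma + epsilon)

    def fixed_point(f, h, it):
        """One exact column update followed by one damped row update."""
        log_col = logsumexp((f[:, None] + h[None, :] - G) / epsilon, axis=0)
        h2 = h + epsilon * (log_g2 - log_col)
        f2 = damp * epsilon * (
            log_g1 - logsumexp((h2[None, :] - G) / epsilon, axis=1))
        if not (np.isfinite(f2).all() and np.isfinite(h2).all()):
            raise FloatingPointError(
                f"non-finite potential at inner iteration {it}")
        return f2, h2

    # The damped alternation alone contracts at rate gamma/(gamma+eps),
    # which is impractically slow when gamma >> eps; Anderson acceleration
    # (memory 5, safeguarded: an extrapolation is kept only if it shrinks
    # the fixed-point residual, otherwise the memory is restarted) restores
    # fast convergence while leaving the fixed point untouched.
    mem = 5
    F_hist: list[np.ndarray] = []
    T_hist: list[np.ndarray] = []
    converged = False
    for it in range(max_inner):
        f_plain, h_plain = fixed_point(f, h, it)
        res_plain = np.abs(f_plain - f).max()
        F_hist.append(f.copy())
        T_hist.append(f_plain.copy())
        if len(F_hist) > mem + 1:
            F_hist.pop(0)
            T_hist.pop(0)
        f, h = f_plain, h_plain
        if len(F_hist) >= 2:
            R = np.array(T_hist) - np.array(F_hist)
            dR = np.diff(R, axis=0)
            gram = dR @ dR.T
            gram += 1e-12 * max(np.trace(gram), 1e-300) * np.eye(len(dR))
            try:
                coef = np.linalg.solve(gram, dR @ R[-1])
                f_acc = T_hist[-1] - coef @ np.diff(np.array(T_hist), axis=0)
            except np.linalg.LinAlgError:
                f_acc = None
            if f_acc is not None and np.isfinite(f_acc).all():
                try:
                    f_try, h_try = fixed_point(f_acc, h_plain, it)
                except FloatingPointError:
                    f_try = None
                if f_try is not None and (
                        np.abs(f_try - f_acc).max() < res_plain):
                    f, h = f_try, h_try
                else:
                    F_hist.clear()
                    T_hist.clear()
        log_col = logsumexp((f[:, None] + h[None, :] - G) / epsilon, axis=0)
        violation = np.abs(np.exp(log_col) - g2).max()
        if violation < inner_tol:
            converged = True
            break
    # final exact column update: the returned coupling is column-feasible
    # to machine precision regardless of where the loop stopped
    log_col = logsumexp((f[:, None] + h[None, :] - G) / epsilon, axis=0)
    h = h + epsilon * (log_g2 - log_col)
    Pi = np.exp((f[:, None] + h[None, :] - G) / epsilon)
    return Pi, f, h, converged


def align(slice1: Slice, slice2: Slice,
          config: Optional[SolverConfig] = None,
          bundle: Optional[CostBundle] = None) -> AlignmentResult:
    """Align two slices and infer the per-spot growth vector.

    Builds the cost bundle, starts from the maximal-entropy product
    coupling, and repeats: linearize the objective at the current coupling,
    solve the linear semi-relaxed problem by Sinkhorn (warm-started duals),
    accept the new coupling — until the relative objective change falls
    below ``outer_tol``.
    """
    config = config or SolverConfig()
    if bundle is None:
        bundle = build_costs(slice1, slice2, metric=config.metric,
                             normalization=config.normalization)
    n1, n2 = bundle.C.shape
    g1 = np.full(n1, 1.0 / n1)
    g2 = np.full(n2, 1.0 / n1)
    # expression-first initialization: solve the doublet-only (linear)
    # problem before bringing in the quadratic merged term.  The quadratic
    # landscape has spurious geometry-matching optima (e.g. mirror
    # alignments of a 1-D tissue) that the product coupling falls into at
    # large alpha; the feature-driven start is deterministic and avoids
    # them without changing any fixed point.
    Pi, f, h, _ = semirelaxed_sinkhorn(
        bundle.C, g1, g2, config.gamma, config.epsilon,
        inner_tol=config.inner_tol, max_inner=config.max_inner)
    trace: list[float] = []
    warnings: list[str] = []
    prev = np.inf
    n_increase = 0
    inner_ok = True
    for it in range(config.max_outer):
        G = ((1.0 - config.alpha) * bundle.C
             + config.alpha * merged_gradient(bundle.M1, bundle.M2, Pi))
        Pi, f, h, ok = semirelaxed_sinkhorn(
            G, g1, g2, config.gamma, config.epsilon,
            inner_tol=config.inner_tol, max_inner=config.max_inner,
            f0=f, h0=h)
        inner_ok = inner_ok and ok
        E = total_objective(bundle, Pi, config.alpha).total
        trace.append(E)
        logger.info("outer %d: objective %.10g", it, E)
        if E > prev + 1e-6 * max(1.0, abs(E)):
            n_increase += 1
            if n_increase > 3:
                warnings.append("objective non-decreasing for >3 outer steps")
                n_increase = 0
        else:
            n_increase = 0
        if abs(E - prev) / max(1.0, abs(E)) < config.outer_tol:
            break
        prev = E
    else:
        warnings.append("outer loop reached max_outer without converging")
    if not inner_ok:
        warnings.append("inner Sinkhorn did not reach inner_tol on some pass")
    xi = Pi.sum(axis=1) - g1
    return AlignmentResult(
        pi=Pi, xi=xi, duals=(f, h), objective_trace=trace,
        params={**asdict(config), "n1": n1, "n2": n2},
        converged=not warnings, warnings=warnings)
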