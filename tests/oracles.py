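"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops or generic numerical optimization,
deliberately independent of the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def triplet_loop(M1, M2, Pi):
    n1, n2 = Pi.shape
    total = 0.0
    for i in range(n1):
        for j in range(n2):
            for k in range(n2):
                total += Pi[i, j] * Pi[i, k] * M2[j, k] ** 2
    for i in range(n1):
        for j in range(n1):
            for k in range(n2):
                total += Pi[i, k] * Pi[j, k] * M1[i, j] ** 2
    return 0.5 * total


def quartet_loop(M1, M2, Pi):
    n1, n2 = Pi.shape
    total = 0.0
    for i in range(n1):
        for j in range(n2):
            for k in range(n1):
                for l in range(n2):
                    total += (M1[i, k] - M2[j, l]) ** 2 * Pi[i, j] * Pi[k, l]
    return total


def doublet_loop(C, Pi):
    total = 0.0
    for i in range(C.shape[0]):
        for j in range(C.shape[1]):
            total += C[i, j] * Pi[i, j]
    return total


def random_instance(rng, n1, n2):
    """Random symmetric zero-diagonal M1/M2 and non-negative Pi."""
    M1 = rng.random((n1, n1))
    M1 = (M1 + M1.T) / 2
    np.fill_diagonal(M1, 0.0)
    M2 = rng.random((n2, n2))
    M2 = (M2 + M2.T) / 2
    np.fill_diagonal(M2, 0.0)
    Pi = rng.random((n1, n2))
    return M1, M2, Pi


def semirelaxed_inner_objective(Pi, G, g1, gamma, epsilon):
    """<G,Pi> + gamma*KL(Pi1||g1) - eps*H(Pi), H(P) = -sum P(logP - 1)."""
    P = np.maximum(Pi, 1e-300)
    r = P.sum(axis=1)
    kl = float(np.sum(r * np.log(r / g1) - r + g1))
    H = -float(np.sum(P * (np.log(P) - 1.0)))
    return float((G * Pi).sum()) + gamma * kl - epsilon * H


def minimize_inner_slsqp(G, g1, g2, gamma, epsilon):
    """Direct numerical minimization over the column-constrained set."""
    n1, n2 = G.shape
    cons = [{"type": "eq",
             "fun": (lambda x, j=j: x.reshape(n1, n2)[:, j].sum() - g2[j])}
            for j in range(n2)]
    x0 = np.full(n1 * n2, g2.sum() / (n1 * n2))
    res = minimize(
        lambda x: semirelaxed_inner_objective(x.reshape(n1, n2), G, g1,
                                              gamma, epsilon),
        x0, method="SLSQP", bounds=[(1e-12, None)] * (n1 * n2),
        constraints=cons, options={"maxiter": 2000, "ftol": 1e-14})
    return res.x.reshape(n1, n2), res.fun


def balanced_sinkhorn_scaling(G, a, b, epsilon, n_iter=20000, tol=1e-14):
    """Classic balanced Sinkhorn in scaling form (total masses must match)."""
    K = np.exp(-G / epsilon)
    u = np.ones_like(a)
    for _ in range(n_iter):
        v = b / (K.T @ u)
        u_new = a / (K @ v)
        if np.abs(u_new - u).max() < tol * np.abs(u).max():
            u = u_new
            break
        u = u_new
    v = b / (K.T @ u)
    return u[:, None] * K * v[None, :]


def migration_loop(S1, S2m, Pi):
    """Column-normalized Pi-weighted mean squared displacement."""
    n1, n2 = Pi.shape
    total = 0.0
    for j in range(n2):
        c = Pi[:, j].sum()
        if c == 0:
            continue
        for i in range(n1):
            d2 = (S1[i, 0] - S2m[j, 0]) ** 2 + (S1[i, 1] - S2m[j, 1]) ** 2
            total += (Pi[i, j] / c) * d2
    return total / n2


def procrustes_grid_best(S1, S2, Pi, n_angles=360):
    """Best weighted objective over a rotation/reflection grid, each with
    the optimal translation for that candidate Q."""
    W = Pi.sum()
    r = Pi.sum(axis=1)
    c = Pi.sum(axis=0)
    mu1 = (r @ S1) / W
    mu2 = (c @ S2) / W
    best = np.inf
    for k in range(n_angles):
        th = 2 * np.pi * k / n_angles
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        for refl in (False, True):
            Q = R @ np.diag([1.0, -1.0]) if refl else R
            S2m = (S2 - mu2) @ Q.T + mu1
            D2 = ((S1[:, None, :] - S2m[None, :, :]) ** 2).sum(-1)
            best = min(best, float((Pi * D2).sum()))
    return best


def procrustes_objective(S1, S2, Pi, Q, h):
    S2m = S2 @ Q.T - h
    D2 = ((S1[:, None, :] - S2m[None, :, :]) ** 2).sum(-1)
    return float((Pi * D2).sum())
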