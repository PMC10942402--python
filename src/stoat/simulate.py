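"""Synthetic spatiotemporal slice pairs with ground-truth correspondence.

Two designs are provided, both with two cell types (A, B) whose relative
proportions change between the timepoints while total spot counts stay
fixed, so a correct alignment must discover growth and death rather than a
shape match.

* 1D: 101 spots on the integer line.  Type A occupies the left end with 30
  spots at t1 and 60 at t2; type B fills the rest (71 then 41).  Each type's
  8-dimensional feature uses four coordinates disjoint from the other
  type's; two of them trace (cos θ, sin θ) with θ linear in the spot's
  fractional position inside its type block, so equal fractional positions
  across timepoints carry identical features.

* 2D: 988 spots on a triangular lattice trimmed to an ellipse.  A vertical
  boundary splits type A (right, 240 spots at t1 → 726 at t2) from type B
  (left, 748 → 262).  Each spot's noiseless feature is the bilinear blend
  λx·f_x,right + (1−λx)·f_x,left + λy·f_y,top + (1−λy)·f_y,bottom of four
  per-type corner vectors, with (λx, λy) the spot's min-max-normalized
  position within its own type's region at its own timepoint — the
  invariant ancestor coordinate.  Zero-mean Gaussian noise of scale sigma
  is added independently per dimension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .slices import Slice

__all__ = [
    "SimulationTruth",
    "simulate_1d",
    "simulate_2d",
    "noise_sweep",
    "type_concordance",
    "DEFAULT_SIGMA_GRID",
]

N_FEATURES = 8
DEFAULT_SIGMA_GRID = tuple(round(0.1 * k, 1) for k in range(1, 9))

# Corner vectors of the 2D design: each type blends four 8-dimensional
# vectors supported on its own half of the feature coordinates, giving a
# smooth within-type gradient and an expression discontinuity at the type
# boundary.  The scale (3, pairwise corner distance 3*sqrt(2)) fixes the
# signal-to-noise meaning of the sigma grid: noise sigma=0.8 produces
# pairwise noise distances (~3.2) comparable to the inter-type contrast,
# so alignment quality degrades toward the end of the grid but not before.
_CORNER_SCALE = 3.0
_CORNERS = {
    "A": {
        "x_right": _CORNER_SCALE * np.eye(N_FEATURES)[0],
        "x_left": _CORNER_SCALE * np.eye(N_FEATURES)[1],
        "y_top": _CORNER_SCALE * np.eye(N_FEATURES)[2],
        "y_bottom": _CORNER_SCALE * np.eye(N_FEATURES)[3],
    },
    "B": {
        "x_right": _CORNER_SCALE * np.eye(N_FEATURES)[4],
        "x_left": _CORNER_SCALE * np.eye(N_FEATURES)[5],
        "y_top": _CORNER_SCALE * np.eye(N_FEATURES)[6],
        "y_bottom": _CORNER_SCALE * np.eye(N_FEATURES)[7],
    },
}


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth emitted alongside a simulated slice pair.

    ``frac1``/``frac2`` hold each spot's fractional (ancestor-invariant)
    coordinate within its type region — a scalar in 1D, an (λx, λy) pair in
    2D.  ``true_growth`` is the per-type growth implied by the designed
    counts; ``sigma``/``seed`` record the noise condition.
    """

    labels1: tuple[str, ...]
    labels2: tuple[str, ...]
    frac1: np.ndarray
    frac2: np.ndarray
    true_growth: dict[str, float]
    sigma: float
    seed: int

    @property
    def n1(self) -> int:
        return len(self.labels1)

    @property
    def n2(self) -> int:
        return len(self.labels2)

    def uniform_coupling(self) -> np.ndarray:
        """Within-type uniform ground-truth coupling.

        Each descendant spot spreads its 1/n1 mass uniformly over all
        same-type ancestors, so every ancestor of type p receives exactly
        the equal-share growth gamma_p; the growth distortion of this
        coupling is identically zero.
        """
        n1, n2 = self.n1, self.n2
        Pi = np.zeros((n1, n2))
        l1 = np.array(self.labels1)
        l2 = np.array(self.labels2)
        for t in dict.fromkeys(self.labels1):
            idx = np.nonzero(l1 == t)[0]
            jdx = np.nonzero(l2 == t)[0]
            if idx.size and jdx.size:
                Pi[np.ix_(idx, jdx)] = 1.0 / (n1 * idx.size)
        return Pi

    def assignment_coupling(self) -> np.ndarray:
        """Nearest-ancestor hard-assignment ground-truth coupling.

        Each descendant's 1/n1 mass goes to the same-type ancestor whose
        fractional coordinate is closest (ties: lowest ancestor index).
        Column-feasible; its growth distortion is the discretization floor
        of the design.
        """
        n1, n2 = self.n1, self.n2
        Pi = np.zeros((n1, n2))
        f1 = self.frac1 if self.frac1.ndim == 2 else self.frac1[:, None]
        f2 = self.frac2 if self.frac2.ndim == 2 else self.frac2[:, None]
        l1 = np.array(self.labels1)
        l2 = np.array(self.labels2)
        for t in dict.fromkeys(self.labels2):
            idx = np.nonzero(l1 == t)[0]
            jdx = np.nonzero(l2 == t)[0]
            if idx.size == 0:
                raise ValueError(f"type {t} has no ancestors at t1")
            d2 = ((f1[idx][:, None, :] - f2[jdx][None, :, :]) ** 2).sum(-1)
            nearest = idx[np.argmin(d2, axis=0)]
            for j, i in zip(jdx, nearest):
                Pi[i, j] = 1.0 / n1
        return Pi


def _growth_from_counts(counts1: dict[str, int], counts2: dict[str, int],
                        n1: int) -> dict[str, float]:
    return {t: (counts2[t] - counts1[t]) / (counts1[t] * n1)
            for t in counts1}


def _features_1d(n_a: int, n_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless 8-dim features for a 1D slice with blocks A then B."""
    n = n_a + n_b
    X = np.zeros((n, N_FEATURES))
    frac = np.zeros(n)
    for t, (lo, hi), base in (("A", (0, n_a), 0), ("B", (n_a, n), 4)):
        m = hi - lo
        lam = np.arange(m) / (m - 1)
        theta = lam * (np.pi / 2)
        X[lo:hi, base + 0] = np.cos(theta)
        X[lo:hi, base + 1] = np.sin(theta)
        X[lo:hi, base + 2] = 1.0
        X[lo:hi, base + 3] = 1.0
        frac[lo:hi] = lam
    return X, frac


def simulate_1d(seed: int = 0) -> tuple[Slice, Slice, SimulationTruth]:
    """One-dimensional two-type design: 101 spots, A 30→60, B 71→41."""
    n = 101
    counts1 = {"A": 30, "B": 71}
    counts2 = {"A": 60, "B": 41}
    coords = np.stack([np.arange(n, dtype=float), np.zeros(n)], axis=1)
    X1, frac1 = _features_1d(counts1["A"], counts1["B"])
    X2, frac2 = _features_1d(counts2["A"], counts2["B"])
    labels1 = ("A",) * counts1["A"] + ("B",) * counts1["B"]
    labels2 = ("A",) * counts2["A"] + ("B",) * counts2["B"]
    s1 = Slice(expression=X1, coords=coords, labels=labels1, timepoint=1.0)
    s2 = Slice(expression=X2, coords=coords, labels=labels2, timepoint=2.0)
    truth = SimulationTruth(
        labels1=labels1, labels2=labels2, frac1=frac1, frac2=frac2,
        true_growth=_growth_from_counts(counts1, counts2, n),
        sigma=0.0, seed=int(seed))
    return s1, s2, truth


def _elliptical_lattice(n_target: int = 988, a: float = 19.0, b: float = 13.0,
                        spacing: float = 0.95) -> np.ndarray:
    """Triangular lattice trimmed to an axis-aligned ellipse.

    Lattice points are ranked by elliptical radius (ties: x then y) and the
    first ``n_target`` taken, so the count is hit exactly and the boundary
    trim is deterministic.
    """
    dy = spacing * np.sqrt(3) / 2
    ny = int(np.ceil((b + 2 * spacing) / dy))
    nx = int(np.ceil((a + 2 * spacing) / spacing))
    pts = []
    for j in range(-ny, ny + 1):
        off = 0.5 * spacing if j % 2 else 0.0
        for i in range(-nx, nx + 1):
            pts.append((i * spacing + off, j * dy))
    P = np.array(pts)
    rho = np.sqrt((P[:, 0] / a) ** 2 + (P[:, 1] / b) ** 2)
    order = np.lexsort((P[:, 1], P[:, 0], np.round(rho, 12)))
    if len(order) < n_target:
        raise ValueError("lattice too small for target spot count")
    sel = order[:n_target]
    return P[sel]


def _assign_types_2d(coords: np.ndarray, n_right: int) -> np.ndarray:
    """Label the ``n_right`` largest-x spots type A (right of a vertical
    boundary), the rest type B; ties broken by lowest x first, then y."""
    order = np.lexsort((coords[:, 1], -coords[:, 0]))
    labels = np.full(len(coords), "B", dtype=object)
    labels[order[:n_right]] = "A"
    return labels


def _features_2d(coords: np.ndarray, labels: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    n = len(coords)
    X = np.zeros((n, N_FEATURES))
    lam = np.zeros((n, 2))
    for t in ("A", "B"):
        idx = np.nonzero(labels == t)[0]
        sub = coords[idx]
        lo = sub.min(axis=0)
        hi = sub.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        lxy = (sub - lo) / span
        cr = _CORNERS[t]
        X[idx] = (lxy[:, :1] * cr["x_right"] + (1 - lxy[:, :1]) * cr["x_left"]
                  + lxy[:, 1:] * cr["y_top"] + (1 - lxy[:, 1:]) * cr["y_bottom"])
        lam[idx] = lxy
    return X, lam


def simulate_2d(sigma: float = 0.0, seed: int = 0
                ) -> tuple[Slice, Slice, SimulationTruth]:
    """Two-dimensional elliptical design: 988 spots, A 240→726, B 748→262."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    n = 988
    counts1 = {"A": 240, "B": 748}
    counts2 = {"A": 726, "B": 262}
    coords = _elliptical_lattice(n)
    lab1 = _assign_types_2d(coords, counts1["A"])
    lab2 = _assign_types_2d(coords, counts2["A"])
    X1, lam1 = _features_2d(coords, lab1)
    X2, lam2 = _features_2d(coords, lab2)
    rng = np.random.default_rng(int(seed))
    if sigma > 0:
        X1 = X1 + rng.normal(0.0, sigma, X1.shape)
        X2 = X2 + rng.normal(0.0, sigma, X2.shape)
    labels1 = tuple(lab1)
    labels2 = tuple(lab2)
    s1 = Slice(expression=X1, coords=coords.copy(), labels=labels1,
               timepoint=1.0)
    s2 = Slice(expression=X2, coords=coords.copy(), labels=labels2,
               timepoint=2.0)
    truth = SimulationTruth(
        labels1=labels1, labels2=labels2, frac1=lam1, frac2=lam2,
        true_growth=_growth_from_counts(counts1, counts2, n),
        sigma=float(sigma), seed=int(seed))
    return s1, s2, truth


def noise_sweep(sigmas: Optional[Sequence[float]] = None,
                seeds: Sequence[int] = (0,)) -> pd.DataFrame:
    """Materialize the 2D design over a noise grid.

    Returns a table with one row per (sigma, seed) holding the slice pair
    and its truth in the ``pair`` column.  Default grid: sigma 0.1 to 0.8
    in increments of 0.1.
    """
    if sigmas is None:
        sigmas = DEFAULT_SIGMA_GRID
    if any(s < 0 for s in sigmas):
        raise ValueError("sigmas must be non-negative")
    rows = []
    for sg in sigmas:
        for sd in seeds:
            rows.append({"sigma": float(sg), "seed": int(sd),
                         "pair": simulate_2d(sigma=sg, seed=sd)})
    return pd.DataFrame(rows, columns=["sigma", "seed", "pair"])


def type_concordance(Pi: np.ndarray, labels1: Sequence[str],
                     labels2: Sequence[str]) -> float:
    """Fraction of coupling mass linking spots of the same cell type."""
    Pi = np.asarray(Pi, dtype=float)
    l1 = np.array([str(x) for x in labels1])
    l2 = np.array([str(x) for x in labels2])
    same = (l1[:, None] == l2[None, :])
    total = Pi.sum()
    if total == 0:
        return 0.0
    return float(Pi[same].sum() / total)
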