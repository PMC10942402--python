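"""Per-spot growth quantities derived from an alignment.

The growth vector ``xi = Pi @ 1 - g1`` is the mass flux of each first-slice
spot across the two timepoints: positive entries mean the spot's lineage
expands (more than one descendant), negative entries that it contracts.
Because columns of ``Pi`` each carry mass ``1/n1``, the entries of ``xi``
always sum to ``(n2 - n1)/n1``, the total normalized change in mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["GrowthVector", "growth_vector", "growth_rate"]


@dataclass(frozen=True)
class GrowthVector:
    """Mass flux per first-slice spot (dimensionless).

    ``dt`` is the time difference ``t2 - t1`` used to convert flux into a
    growth rate; it defaults to 1 (per-interval rate) when unset.
    """

    xi: np.ndarray
    n1: int
    dt: Optional[float] = None

    def __post_init__(self) -> None:
        xi = np.asarray(self.xi, dtype=float)
        if xi.ndim != 1 or xi.shape[0] != self.n1:
            raise ValueError("xi must be a length-n1 vector")
        if (xi < -1.0 / self.n1 - 1e-12).any():
            raise ValueError("growth entries cannot be below -1/n1")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "xi", xi)

    @property
    def growing(self) -> np.ndarray:
        """Boolean mask of spots gaining mass (reporting only)."""
        return self.xi > 0

    @property
    def dying(self) -> np.ndarray:
        return self.xi < 0


def growth_vector(Pi: np.ndarray, g1: Optional[np.ndarray] = None,
                  dt: Optional[float] = None) -> GrowthVector:
    """xi = Pi @ 1 - g1 for a column-feasible coupling."""
    Pi = np.asarray(Pi, dtype=float)
    if (Pi < 0).any():
        raise ValueError("Pi must be non-negative")
    n1 = Pi.shape[0]
    if g1 is None:
        g1 = np.full(n1, 1.0 / n1)
    g1 = np.asarray(g1, dtype=float)
    if g1.shape != (n1,):
        raise ValueError(f"g1 must have length {n1}")
    return GrowthVector(xi=Pi.sum(axis=1) - g1, n1=n1, dt=dt)


def growth_rate(gv: GrowthVector) -> np.ndarray:
    """Per-spot log growth rate J_i = log(1 + n1*xi_i) / dt.

    ``1 + n1*xi_i`` is the spot's descendant count in cell units; a spot
    whose mass doubles (xi = 1/n1) has J = log 2 per unit time.  A spot with
    ``1 + n1*xi_i <= 0`` has lost all of its mass and the rate is undefined.
    """
    dt = 1.0 if gv.dt is None else gv.dt
    arg = 1.0 + gv.n1 * gv.xi
    bad = np.nonzero(arg <= 0)[0]
    if bad.size:
        raise ValueError(
            f"growth rate undefined for extinct spot {int(bad[0])} "
            f"(1 + n1*xi <= 0)")
    return np.log(arg) / dt
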