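"""Boltzmann inversion of distributions into tabulated potentials.

The potential of mean force is the direct inversion U(r) = -kB T ln g(r)
of a radial distribution function; applied to bond-length and angle
histograms it yields the bonded terms U(l) = -kB T ln P(l) and
U(theta) = -kB T ln P(theta).  No Jacobian corrections (4 pi r^2 for
distances, sin theta for angles) are applied: the inversion is the
literal logarithm of the measured distribution, and the table headers
record that convention so files are self-describing.

Bins where the distribution falls below ``G_FLOOR`` are unsampled.  The
inner core is filled with a linear repulsive wall extrapolated from the
innermost sampled slope; interior gaps are bridged by linear
interpolation.  Non-bonded potentials are truncated and shifted so that
U(r_cut) = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .distributions import TabulatedFunction
from .units import thermal_energy

logger = logging.getLogger(__name__)

#: Distribution values at or below this are treated as unsampled.
G_FLOOR = 1e-6

#: Fallback wall steepness (kJ/mol per nm or per degree) when the
#: innermost sampled slope is not repulsive.
FALLBACK_WALL_SLOPE = 1000.0


@dataclass
class PotentialTable:
    """Tabulated potential U and force F = -dU/dx on a uniform grid.

    For non-bonded tables ``r_cut`` marks the truncation radius:
    U(r_cut) = 0 and F(r_cut) = 0, and both vanish beyond it.  Bonded
    tables (bond length, angle) have ``r_cut=None`` and extrapolate
    linearly outside the grid.  ``r_core`` is the lower edge of the
    sampled region; below it the potential is the extrapolated wall.
    """

    x0: float
    dx: float
    U: np.ndarray
    F: np.ndarray
    r_core: float = 0.0
    r_cut: float | None = None
    kind: str = "potential"
    n_wall_clamps: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.dx <= 0:
            raise ValueError("grid spacing must be positive")
        if len(self.U) != len(self.F):
            raise ValueError("U and F columns differ in length")
        if not np.all(np.isfinite(self.U)):
            raise ValueError("potential table contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.U)

    @property
    def x(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.n)

    @property
    def x_max(self) -> float:
        return self.x0 + self.dx * (self.n - 1)

    def copy(self) -> "PotentialTable":
        return PotentialTable(
            self.x0, self.dx, self.U.copy(), self.F.copy(),
            self.r_core, self.r_cut, self.kind,
        )

    def energy(self, r: np.ndarray | float) -> np.ndarray | float:
        """Interpolated energy; wall-extrapolated below the grid,
        zero beyond r_cut (or linearly extrapolated if uncut)."""
        scalar = np.isscalar(r)
        r = np.atleast_1d(np.asarray(r, dtype=float))
        u = np.interp(r, self.x, self.U)
        below = r < self.x0
        if np.any(below):
            self.n_wall_clamps += int(below.sum())
            u[below] = self.U[0] + self.F[0] * (self.x0 - r[below])
        above = r > self.x_max
        if np.any(above):
            if self.r_cut is not None:
                u[above] = 0.0
            else:
                u[above] = self.U[-1] - self.F[-1] * (r[above] - self.x_max)
        return float(u[0]) if scalar else u

    def force(self, r: np.ndarray | float) -> np.ndarray | float:
        """Interpolated force magnitude along the coordinate."""
        scalar = np.isscalar(r)
        r = np.atleast_1d(np.asarray(r, dtype=float))
        f = np.interp(r, self.x, self.F)
        below = r < self.x0
        if np.any(below):
            self.n_wall_clamps += int(below.sum())
            f[below] = self.F[0]
        above = r > self.x_max
        if np.any(above):
            f[above] = 0.0 if self.r_cut is not None else self.F[-1]
        return float(f[0]) if scalar else f

    def as_tabulated(self) -> TabulatedFunction:
        return TabulatedFunction(self.x0, self.dx, self.U.copy(), "potential")


def central_difference_force(x0: float, dx: float, U: np.ndarray) -> np.ndarray:
    """F = -dU/dx by central differences, one-sided at the edges."""
    F = np.empty_like(U)
    F[1:-1] = -(U[2:] - U[:-2]) / (2 * dx)
    F[0] = -(U[1] - U[0]) / dx
    F[-1] = -(U[-1] - U[-2]) / dx
    return F


def _fill_unsampled(x: np.ndarray, U: np.ndarray, valid: np.ndarray,
                    dx: float) -> tuple[np.ndarray, float]:
    """Complete a partially defined potential over unsampled bins.

    Interior gaps are linearly interpolated; the inner core gets a
    linear repulsive wall continuing the innermost sampled slope (a
    steep fallback wall if that slope is not repulsive); the outer end
    continues its last sampled slope.  Returns the filled table and
    r_core, the first sampled grid point.
    """
    if not np.any(valid):
        raise ValueError("distribution is unsampled everywhere; nothing to invert")
    idx = np.flatnonzero(valid)
    i0, i1 = idx[0], idx[-1]
    filled = np.array(U, dtype=float)
    # interior gaps
    interior = ~valid[i0 : i1 + 1]
    if np.any(interior):
        inside = np.arange(i0, i1 + 1)
        filled[inside[interior]] = np.interp(
            x[inside[interior]], x[idx], U[idx]
        )
    # inner wall: dU/dr must be negative (repulsive) approaching contact
    if i0 > 0:
        if i1 > i0:
            slope = (filled[i0 + 1] - filled[i0]) / dx
        else:
            slope = 0.0
        if slope >= 0:
            slope = -FALLBACK_WALL_SLOPE
            logger.debug("innermost sampled slope not repulsive; using fallback wall")
        filled[:i0] = filled[i0] + slope * (x[:i0] - x[i0])
    # outer end
    if i1 < len(U) - 1:
        slope = (filled[i1] - filled[i1 - 1]) / dx if i1 > i0 else 0.0
        filled[i1 + 1 :] = filled[i1] + slope * (x[i1 + 1 :] - x[i1])
    return filled, float(x[i0])


def apply_cutoff(x: np.ndarray, U: np.ndarray, r_cut: float,
                 dx: float) -> np.ndarray:
    """Truncate and shift: subtract U(r_cut), zero everything beyond."""
    shift = np.interp(r_cut, x, U)
    out = U - shift
    out[x >= r_cut - 1e-12] = 0.0
    return out


def pmf_from_rdf(
    g: TabulatedFunction, T: float, r_cut: float, g_floor: float = G_FLOOR
) -> PotentialTable:
    """Potential of mean force U = -kB T ln g, truncated-shifted at r_cut.

    The PMF of the target RDF is the standard zeroth-order CG potential
    and the starting point of the iterative refinement.
    """
    kT = thermal_energy(T)
    x = g.x
    if not (x[0] <= r_cut <= x[-1] + g.dx):
        raise ValueError(f"r_cut={r_cut} nm outside the RDF grid [{x[0]}, {x[-1]}]")
    valid = g.values > g_floor
    with np.errstate(divide="ignore"):
        U_raw = np.where(valid, -kT * np.log(np.where(valid, g.values, 1.0)), 0.0)
    U, r_core = _fill_unsampled(x, U_raw, valid, g.dx)
    U = apply_cutoff(x, U, r_cut, g.dx)
    F = central_difference_force(g.x0, g.dx, U)
    F[x >= r_cut - 1e-12] = 0.0
    return PotentialTable(g.x0, g.dx, U, F, r_core=r_core, r_cut=r_cut)


def _bonded_inversion(P: TabulatedFunction, T: float,
                      g_floor: float) -> PotentialTable:
    kT = thermal_energy(T)
    x = P.x
    valid = P.values > g_floor
    with np.errstate(divide="ignore"):
        U_raw = np.where(valid, -kT * np.log(np.where(valid, P.values, 1.0)), 0.0)
    U, r_core = _fill_unsampled(x, U_raw, valid, P.dx)
    U = U - U.min()
    F = central_difference_force(P.x0, P.dx, U)
    return PotentialTable(P.x0, P.dx, U, F, r_core=r_core, r_cut=None)


def potential_from_bond_dist(
    P: TabulatedFunction, T: float, g_floor: float = G_FLOOR
) -> PotentialTable:
    """Bond potential U(l) = -kB T ln P(l), minimum shifted to zero.

    Bonded terms are extracted once from the reference ensemble and are
    not refined by the iteration.
    """
    if P.kind != "bond_dist":
        raise ValueError("expected a bond_dist table")
    return _bonded_inversion(P, T, g_floor)


def potential_from_angle_dist(
    P: TabulatedFunction, T: float, g_floor: float = G_FLOOR
) -> PotentialTable:
    """Angle potential U(theta) = -kB T ln P(theta) on the degree grid."""
    if P.kind != "angle_dist":
        raise ValueError("expected an angle_dist table")
    return _bonded_inversion(P, T, g_floor)


def force_from_potential(pt: PotentialTable) -> PotentialTable:
    """Rebuild the force column F = -dU/dx by central differences."""
    out = pt.copy()
    out.F = central_difference_force(pt.x0, pt.dx, pt.U)
    if pt.r_cut is not None:
        out.F[out.x >= pt.r_cut - 1e-12] = 0.0
    return out
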