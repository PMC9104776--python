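"""Structural distributions measured on CG trajectories.

Three estimators feed the Boltzmann-inversion pipeline: the pair radial
distribution function g(r) between two bead-type sets, the bond-length
distribution P(l), and the bending-angle distribution P(theta).  All
distances and angles are evaluated under the minimum-image convention
in an orthorhombic box.

Grid convention: histograms use bin edges x0 + i*dx and report values
at bin midpoints, so ``TabulatedFunction.x`` starts at x0 + dx/2.  The
RDF is normalized by the ideal-gas shell expectation N_a * rho_b *
V_shell averaged over frames; this estimator is part of the on-disk
contract — target and iterate must be measured with the same one for
the iterative matching to have a well-defined fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import savgol_filter

from . import _kernels
from .mapping import CGFrame
from .pbc import minimum_image

logger = logging.getLogger(__name__)

DISTRIBUTION_KINDS = ("rdf", "bond_dist", "angle_dist")
TABLE_KINDS = DISTRIBUTION_KINDS + ("potential", "force")


@dataclass
class TabulatedFunction:
    """A function sampled on a uniform grid x_i = x0 + i*dx."""

    x0: float
    dx: float
    values: np.ndarray
    kind: str = "rdf"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dx <= 0:
            raise ValueError("grid spacing dx must be positive")
        if self.kind not in TABLE_KINDS:
            raise ValueError(f"unknown table kind {self.kind!r}")
        if self.kind in DISTRIBUTION_KINDS and np.any(self.values < 0):
            raise ValueError(f"{self.kind} values must be non-negative")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def x(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.n)

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation, clamped at the grid ends."""
        return np.interp(x, self.x, self.values)

    def copy(self) -> "TabulatedFunction":
        return TabulatedFunction(self.x0, self.dx, self.values.copy(), self.kind)

    def integral(self) -> float:
        """Trapezoidal integral over the grid."""
        return float(np.trapezoid(self.values, dx=self.dx))

    def normalized(self) -> "TabulatedFunction":
        """Rescale so the trapezoidal integral equals one."""
        total = self.integral()
        if total <= 0:
            raise ValueError("cannot normalize a table with non-positive integral")
        return TabulatedFunction(self.x0, self.dx, self.values / total, self.kind)

    def same_grid(self, other: "TabulatedFunction", tol: float = 1e-9) -> bool:
        return (
            self.n == other.n
            and abs(self.x0 - other.x0) <= tol
            and abs(self.dx - other.dx) <= tol
        )


def _type_indices(bead_types: Sequence[str], wanted: Iterable[str]) -> np.ndarray:
    wanted = set([wanted] if isinstance(wanted, str) else wanted)
    return np.array([i for i, t in enumerate(bead_types) if t in wanted], dtype=int)


def _pair_arrays(
    idx_a: np.ndarray, idx_b: np.ndarray, exclusions: set[tuple[int, int]] | None
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Distinct pairs between two index sets, each unordered pair once.

    Identical sets give the upper triangle; disjoint sets give the full
    product.  Partially overlapping sets are rejected — the ideal-gas
    normalization below is only defined for those two cases.
    """
    set_a, set_b = set(idx_a.tolist()), set(idx_b.tolist())
    if set_a == set_b:
        ii, jj = np.triu_indices(len(idx_a), k=1)
        pi, pj = idx_a[ii], idx_a[jj]
        same = True
    elif set_a.isdisjoint(set_b):
        pi = np.repeat(idx_a, len(idx_b))
        pj = np.tile(idx_b, len(idx_a))
        same = False
    else:
        raise ValueError("type sets must be identical or disjoint")
    if exclusions:
        excl = {(min(i, j), max(i, j)) for i, j in exclusions}
        keep = np.array(
            [(min(i, j), max(i, j)) not in excl for i, j in zip(pi, pj)], dtype=bool
        )
        pi, pj = pi[keep], pj[keep]
    return pi, pj, same


def radial_distribution(
    frames: Sequence[CGFrame],
    types_a: Iterable[str] | str,
    types_b: Iterable[str] | str,
    r_max: float,
    dx: float = 0.01,
    exclusions: set[tuple[int, int]] | None = None,
) -> TabulatedFunction:
    """Pair radial distribution function g(r) between two bead-type sets.

    Counts minimum-image pair distances into bins of width dx up to
    r_max and divides by the ideal-gas expectation for each spherical
    shell; bonded pairs listed in ``exclusions`` are skipped.  r_max
    must not exceed half the shortest box edge.
    """
    if not frames:
        raise ValueError("need at least one frame")
    box = frames[0].box
    if r_max > box.min() / 2 + 1e-12:
        raise ValueError(
            f"r_max={r_max} nm exceeds half the shortest box edge ({box.min() / 2} nm)"
        )
    idx_a = _type_indices(frames[0].bead_types, types_a)
    idx_b = _type_indices(frames[0].bead_types, types_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("no beads found for one of the requested type sets")
    pi, pj, same = _pair_arrays(idx_a, idx_b, exclusions)
    if len(pi) == 0:
        raise ValueError("no pairs left after exclusions")

    edges = np.arange(0.0, r_max + dx / 2, dx)
    counts = np.zeros(len(edges) - 1)
    if _kernels.HAVE_NUMBA:
        for frame in frames:
            _kernels.pair_distance_counts(
                frame.positions, frame.box, pi, pj, float(r_max), float(dx), counts
            )
    else:
        for frame in frames:
            d = minimum_image(frame.positions[pi] - frame.positions[pj], frame.box)
            r = np.linalg.norm(d, axis=1)
            counts += np.histogram(r, bins=edges)[0]
    counts /= len(frames)

    volume = float(np.prod(box))
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    if same:
        n_pairs_ideal = len(idx_a) * (len(idx_a) - 1) / 2.0
    else:
        n_pairs_ideal = len(idx_a) * len(idx_b)
    ideal = n_pairs_ideal * shell / volume
    g = counts / ideal
    return TabulatedFunction(dx / 2.0, dx, g, "rdf")


def bond_distribution(
    frames: Sequence[CGFrame],
    bond_pairs: Sequence[tuple[int, int]],
    l_max: float,
    dx: float = 0.002,
) -> TabulatedFunction:
    """Normalized histogram of minimum-image bond lengths P(l)."""
    if not bond_pairs:
        raise ValueError("bond list is empty")
    bi = np.array([b[0] for b in bond_pairs], dtype=int)
    bj = np.array([b[1] for b in bond_pairs], dtype=int)
    edges = np.arange(0.0, l_max + dx / 2, dx)
    counts = np.zeros(len(edges) - 1)
    for frame in frames:
        d = minimum_image(frame.positions[bi] - frame.positions[bj], frame.box)
        counts += np.histogram(np.linalg.norm(d, axis=1), bins=edges)[0]
    if counts.sum() == 0:
        raise ValueError("no bond lengths fell inside [0, l_max]")
    table = TabulatedFunction(dx / 2.0, dx, counts, "bond_dist")
    return table.normalized()


def bead_angle(
    frame: CGFrame, i: int, j: int, k: int, degrees: bool = True
) -> float:
    """Angle at middle bead j of the triple (i, j, k), minimum image."""
    u = minimum_image(frame.positions[i] - frame.positions[j], frame.box)
    v = minimum_image(frame.positions[k] - frame.positions[j], frame.box)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ZeroDivisionError("degenerate zero-length angle arm")
    c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    theta = np.arccos(c)
    return float(np.degrees(theta)) if degrees else float(theta)


def angle_distribution(
    frames: Sequence[CGFrame],
    angle_triples: Sequence[tuple[int, int, int]],
    dtheta: float = 1.0,
) -> TabulatedFunction:
    """Normalized histogram of bending angles P(theta), theta in degrees.

    The grid spans [0, 180] degrees.  Triples with a zero-length arm
    are skipped and counted in the log.
    """
    if not angle_triples:
        raise ValueError("angle list is empty")
    ai = np.array([a[0] for a in angle_triples], dtype=int)
    aj = np.array([a[1] for a in angle_triples], dtype=int)
    ak = np.array([a[2] for a in angle_triples], dtype=int)
    edges = np.arange(0.0, 180.0 + dtheta / 2, dtheta)
    counts = np.zeros(len(edges) - 1)
    skipped = 0
    for frame in frames:
        u = minimum_image(frame.positions[ai] - frame.positions[aj], frame.box)
        v = minimum_image(frame.positions[ak] - frame.positions[aj], frame.box)
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        ok = (nu > 0) & (nv > 0)
        skipped += int((~ok).sum())
        c = np.clip(np.sum(u[ok] * v[ok], axis=1) / (nu[ok] * nv[ok]), -1.0, 1.0)
        theta = np.degrees(np.arccos(c))
        counts += np.histogram(theta, bins=edges)[0]
    if skipped:
        logger.warning("skipped %d degenerate angle triples", skipped)
    if counts.sum() == 0:
        raise ValueError("no angles measured")
    table = TabulatedFunction(dtheta / 2.0, dtheta, counts, "angle_dist")
    return table.normalized()


def smooth_table(
    f: TabulatedFunction, method: str = "savgol", window: int = 5
) -> TabulatedFunction:
    """Smooth a table on its grid, preserving the two endpoints.

    ``savgol`` applies a quadratic Savitzky-Golay filter, ``moving`` a
    flat moving average.  Distribution kinds are clamped at zero after
    filtering so smoothing never produces negative densities.
    """
    if window > f.n:
        raise ValueError(f"window {window} exceeds table length {f.n}")
    if window < 3:
        raise ValueError("window must be at least 3")
    if window % 2 == 0:
        window += 1
    if method == "savgol":
        smoothed = savgol_filter(f.values, window, polyorder=2)
    elif method == "moving":
        kernel = np.ones(window) / window
        smoothed = np.convolve(
            np.pad(f.values, window // 2, mode="edge"), kernel, mode="valid"
        )
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    smoothed[0] = f.values[0]
    smoothed[-1] = f.values[-1]
    if f.kind in DISTRIBUTION_KINDS:
        smoothed = np.clip(smoothed, 0.0, None)
    return TabulatedFunction(f.x0, f.dx, smoothed, f.kind)
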