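"""NVT coarse-grained molecular dynamics with tabulated potentials.

Beads interact through tabulated non-bonded pair potentials (looked up
per type pair), tabulated bond-length potentials, and tabulated bending
potentials; forces are linear interpolations of the stored F column.
Integration is leapfrog (velocities staggered half a step behind
positions) in a periodic orthorhombic box.  Temperature is held with
either the canonical stochastic velocity-rescaling (CSVR) thermostat or
the Berendsen weak-coupling scheme.

Units are GROMACS-consistent (nm, ps, amu, kJ/mol): a force of
1 kJ/(mol nm) on a 1 amu bead gives exactly 1 nm/ps^2, so the equations
of motion carry no conversion factors.  The center-of-mass motion of
the mobile beads is removed every step so velocity rescaling cannot
pump energy into a drifting box ("flying ice cube").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .inversion import PotentialTable
from .mapping import CGFrame
from .pbc import minimum_image, wrap_positions
from .units import KB


class ConfigurationError(ValueError):
    """System and potential assignments are inconsistent."""


class IntegrationBlowup(RuntimeError):
    """Non-finite coordinates appeared during integration."""


#: Use the numba pair kernel when available; the numpy fallback is the
#: reference implementation and can be forced by flipping this flag.
USE_NUMBA = _kernels.HAVE_NUMBA


def pair_key(type_a: str, type_b: str) -> tuple[str, str]:
    """Canonical (sorted) key for a non-bonded type pair."""
    return (type_a, type_b) if type_a <= type_b else (type_b, type_a)


@dataclass
class SimulationConfig:
    """Integration and thermostat settings for one NVT run."""

    dt: float = 0.001           # ps
    n_steps: int = 100_000
    T_ref: float = 330.0        # K
    thermostat: str = "vrescale"  # vrescale | berendsen | none
    tau_T: float = 0.1          # ps
    r_cut: float = 1.0          # nm
    seed: int = 0
    sample_interval: int = 100  # steps between stored frames

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        if self.thermostat not in ("vrescale", "berendsen", "none"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.thermostat != "none" and (self.T_ref <= 0 or self.tau_T <= 0):
            raise ValueError("thermostat needs positive T_ref and tau_T")


@dataclass
class CGSystem:
    """Bead coordinates, topology and potential assignments.

    ``nonbonded`` maps canonical type-pair keys to a PotentialTable or
    to None for an explicit "no interaction"; a type pair occurring in
    the system without any entry is a configuration error.  Bonded
    pairs (and angle end pairs) are added to ``exclusions``
    automatically.
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    bead_types: list[str]
    box: np.ndarray
    bonds: list[tuple[int, int, PotentialTable]] = field(default_factory=list)
    angles: list[tuple[int, int, int, PotentialTable]] = field(default_factory=list)
    nonbonded: dict[tuple[str, str], PotentialTable | None] = field(default_factory=dict)
    exclusions: set[tuple[int, int]] = field(default_factory=set)
    frozen: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.frozen is None:
            self.frozen = np.zeros(self.n_beads, dtype=bool)
        self.frozen = np.asarray(self.frozen, dtype=bool)
        for i, j, _ in self.bonds:
            if i == j:
                raise ConfigurationError(f"self-bond on bead {i}")
            self.exclusions.add((min(i, j), max(i, j)))
        for i, j, k, _ in self.angles:
            if len({i, j, k}) != 3:
                raise ConfigurationError(f"degenerate angle ({i},{j},{k})")
            self.exclusions.add((min(i, k), max(i, k)))
        self.exclusions = {(min(i, j), max(i, j)) for i, j in self.exclusions}

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def mobile(self) -> np.ndarray:
        return ~self.frozen

    def copy(self) -> "CGSystem":
        return CGSystem(
            self.positions.copy(), self.velocities.copy(), self.masses.copy(),
            list(self.bead_types), self.box.copy(),
            list(self.bonds), list(self.angles), dict(self.nonbonded),
            set(self.exclusions), self.frozen.copy(),
        )

    def as_frame(self) -> CGFrame:
        return CGFrame(self.positions.copy(), self.masses.copy(),
                       list(self.bead_types), self.box.copy())


class _PairCache:
    """Precomputed index lists for the all-pairs non-bonded loop and
    grouped bond/angle evaluation; topology-static, table-dynamic."""

    def __init__(self, system: CGSystem) -> None:
        types = np.asarray(system.bead_types)
        unique = sorted(set(system.bead_types))
        # every occurring type pair must be declared (table or None)
        for a in range(len(unique)):
            for b in range(a, len(unique)):
                key = pair_key(unique[a], unique[b])
                n_a = int((types == key[0]).sum())
                n_b = int((types == key[1]).sum())
                pair_exists = n_a * n_b > 1 if key[0] == key[1] else n_a * n_b > 0
                if pair_exists and key not in system.nonbonded:
                    raise ConfigurationError(
                        f"no non-bonded assignment for type pair {key} "
                        "(use None for no interaction)"
                    )
        excl = system.exclusions
        self.groups: list[tuple[tuple[str, str], np.ndarray, np.ndarray]] = []
        for key, table in system.nonbonded.items():
            if table is None:
                continue
            ia = np.flatnonzero(types == key[0])
            ib = np.flatnonzero(types == key[1])
            if key[0] == key[1]:
                ii, jj = np.triu_indices(len(ia), k=1)
                pi, pj = ia[ii], ia[jj]
            else:
                pi = np.repeat(ia, len(ib))
                pj = np.tile(ib, len(ia))
            if len(pi) == 0:
                continue
            keep = np.array(
                [(min(i, j), max(i, j)) not in excl for i, j in zip(pi, pj)],
                dtype=bool,
            )
            pi, pj = pi[keep], pj[keep]
            if len(pi):
                self.groups.append((key, pi, pj))
        # bonds grouped by shared table
        by_table: dict[int, tuple[PotentialTable, list[int], list[int]]] = {}
        for i, j, table in system.bonds:
            rec = by_table.setdefault(id(table), (table, [], []))
            rec[1].append(i)
            rec[2].append(j)
        self.bond_groups = [
            (t, np.array(bi), np.array(bj)) for t, bi, bj in by_table.values()
        ]
        by_table_a: dict[int, tuple[PotentialTable, list, list, list]] = {}
        for i, j, k, table in system.angles:
            rec = by_table_a.setdefault(id(table), (table, [], [], []))
            rec[1].append(i)
            rec[2].append(j)
            rec[3].append(k)
        self.angle_groups = [
            (t, np.array(ai), np.array(aj), np.array(ak))
            for t, ai, aj, ak in by_table_a.values()
        ]


def compute_forces(
    system: CGSystem, cache: _PairCache | None = None
) -> tuple[np.ndarray, float]:
    """Forces on every bead (kJ/(mol nm)) and the total potential energy.

    Pairwise minimum-image forces obey Newton's third law exactly;
    frozen beads accumulate force like any other (the integrator simply
    never moves them).
    """
    if cache is None:
        cache = _PairCache(system)
    n = system.n_beads
    forces = np.zeros((n, 3))
    energy = 0.0
    pos, box = system.positions, system.box

    def _accumulate_pairs(table: PotentialTable, pi: np.ndarray, pj: np.ndarray) -> float:
        if USE_NUMBA:
            return _kernels.pair_forces(
                pos, box, pi, pj, table.x0, table.dx, table.U, table.F,
                table.r_cut is not None, forces,
            )
        d = minimum_image(pos[pi] - pos[pj], box)
        r = np.linalg.norm(d, axis=1)
        f_mag = table.force(r)
        e = float(table.energy(r).sum())
        fvec = (f_mag / np.where(r > 1e-12, r, 1.0))[:, None] * d
        for c in range(3):
            forces[:, c] += np.bincount(pi, weights=fvec[:, c], minlength=n)
            forces[:, c] -= np.bincount(pj, weights=fvec[:, c], minlength=n)
        return e

    for key, pi, pj in cache.groups:
        energy += _accumulate_pairs(system.nonbonded[key], pi, pj)

    for table, bi, bj in cache.bond_groups:
        energy += _accumulate_pairs(table, bi, bj)

    deg = 180.0 / math.pi
    for table, ai, aj, ak in cache.angle_groups:
        u = minimum_image(pos[ai] - pos[aj], box)
        v = minimum_image(pos[ak] - pos[aj], box)
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        c_th = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
        theta = np.degrees(np.arccos(c_th))
        energy += float(table.energy(theta).sum())
        # table F column is -dU/dtheta per degree; convert to per radian
        dU_dth = -table.force(theta) * deg
        sin_th = np.sqrt(np.clip(1.0 - c_th**2, 0.0, None))
        ok = sin_th > 1e-8
        pref = np.where(ok, dU_dth / np.where(ok, sin_th, 1.0), 0.0)
        fi = pref[:, None] * (v / (nu * nv)[:, None] - c_th[:, None] * u / (nu**2)[:, None])
        fk = pref[:, None] * (u / (nu * nv)[:, None] - c_th[:, None] * v / (nv**2)[:, None])
        for c in range(3):
            forces[:, c] += np.bincount(ai, weights=fi[:, c], minlength=n)
            forces[:, c] += np.bincount(ak, weights=fk[:, c], minlength=n)
            forces[:, c] -= np.bincount(aj, weights=(fi + fk)[:, c], minlength=n)

    return forces, energy


def leapfrog_step(
    system: CGSystem, config: SimulationConfig, forces: np.ndarray, step: int = 0
) -> CGSystem:
    """Advance one leapfrog step in place.

    v(t + dt/2) = v(t - dt/2) + (F/m) dt, then x(t + dt) = x(t) +
    v(t + dt/2) dt; positions are wrapped back into the box.  Frozen
    beads never move.
    """
    mob = system.mobile
    system.velocities[mob] += forces[mob] / system.masses[mob, None] * config.dt
    system.velocities[system.frozen] = 0.0
    system.positions[mob] += system.velocities[mob] * config.dt
    system.positions[:] = wrap_positions(system.positions, system.box)
    if not np.all(np.isfinite(system.positions)):
        bad = np.flatnonzero(~np.isfinite(system.positions).all(axis=1))
        raise IntegrationBlowup(
            f"non-finite coordinates at step {step} for beads {bad.tolist()}"
        )
    return system


def _n_dof(n_mobile: int) -> int:
    # three translational dof removed with the COM; a single mobile
    # bead keeps its own three
    return 3 * n_mobile - 3 if n_mobile > 1 else 3


def kinetic_energy(system: CGSystem) -> float:
    """Total kinetic energy of mobile beads, kJ/mol."""
    mob = system.mobile
    v = system.velocities[mob]
    return 0.5 * float(np.sum(system.masses[mob] * np.sum(v * v, axis=1)))


def instantaneous_temperature(system: CGSystem) -> float:
    """Kinetic temperature T = 2 K / (N_df kB) of the mobile beads."""
    n_mobile = int(system.mobile.sum())
    if n_mobile == 0:
        raise ValueError("no mobile beads")
    return 2.0 * kinetic_energy(system) / (_n_dof(n_mobile) * KB)


def remove_com_motion(system: CGSystem) -> None:
    """Zero the center-of-mass momentum of the mobile subsystem."""
    mob = system.mobile
    if int(mob.sum()) < 2:
        return
    m = system.masses[mob]
    p = m @ system.velocities[mob]
    system.velocities[mob] -= p / m.sum()


def vrescale_thermostat(
    system: CGSystem, config: SimulationConfig, rng: np.random.Generator
) -> None:
    """Canonical stochastic velocity rescaling (CSVR).

    The kinetic energy is propagated one step of the exact stochastic
    dynamics whose stationary distribution is the canonical one, then
    all mobile velocities are scaled by a common factor.  In the
    tau_T -> infinity limit velocities are untouched.
    """
    n_mobile = int(system.mobile.sum())
    nf = _n_dof(n_mobile)
    K = kinetic_energy(system)
    if K == 0.0:
        return
    if math.isinf(config.tau_T):
        return
    c = math.exp(-config.dt / config.tau_T)
    K_bar = 0.5 * nf * KB * config.T_ref
    r1 = rng.standard_normal()
    s = rng.chisquare(nf - 1) if nf > 1 else 0.0
    K_new = (
        K
        + (1.0 - c) * (K_bar * (r1 * r1 + s) / nf - K)
        + 2.0 * r1 * math.sqrt(K * K_bar / nf * (1.0 - c) * c)
    )
    K_new = max(K_new, 0.0)
    system.velocities[system.mobile] *= math.sqrt(K_new / K)


def berendsen_thermostat(system: CGSystem, config: SimulationConfig) -> None:
    """Berendsen weak coupling: scale by sqrt(1 + dt/tau (T_ref/T - 1))."""
    if not system.mobile.any():
        return
    T = instantaneous_temperature(system)
    if T == 0.0:
        return
    lam = math.sqrt(1.0 + (config.dt / config.tau_T) * (config.T_ref / T - 1.0))
    system.velocities[system.mobile] *= lam


def initialize_velocities(
    system: CGSystem, T: float, rng: np.random.Generator
) -> None:
    """Draw Maxwell-Boltzmann velocities at T, remove COM drift, and
    rescale so the instantaneous temperature is exactly T."""
    n = system.n_beads
    sigma = np.sqrt(KB * T / system.masses)[:, None]
    system.velocities = sigma * rng.standard_normal((n, 3))
    system.velocities[system.frozen] = 0.0
    remove_com_motion(system)
    T_now = instantaneous_temperature(system)
    if T_now > 0:
        system.velocities[system.mobile] *= math.sqrt(T / T_now)


@dataclass
class SimResult:
    """Sampled trajectory and scalar time series of one NVT run."""

    frames: list[CGFrame]
    times: np.ndarray          # ps
    temperature: np.ndarray    # K, at sample points
    potential: np.ndarray      # kJ/mol
    kinetic: np.ndarray        # kJ/mol
    final_system: CGSystem


def _fused_loop_applicable(system: CGSystem, config: SimulationConfig) -> bool:
    return (
        USE_NUMBA
        and not system.bonds
        and not system.angles
        and not system.exclusions
        and not bool(system.frozen.any())
        and config.thermostat in ("vrescale", "none")
        and sum(t is not None for t in system.nonbonded.values()) == 1
    )


def _run_nvt_fused(
    system: CGSystem, config: SimulationConfig, cache: _PairCache
) -> SimResult:
    """Numba fused step loop for single-table, all-mobile systems.

    Same step order and physics as the generic loop; thermostat
    randoms are pre-drawn in vectorized order from config.seed, so
    this path is reproducible on its own (and statistically, but not
    bitwise, identical to the generic path).
    """
    rng = np.random.default_rng(config.seed)
    key, pi, pj = cache.groups[0]
    table = system.nonbonded[key]
    nf = _n_dof(system.n_beads)
    n_samples = config.n_steps // config.sample_interval
    out_pos = np.empty((n_samples, system.n_beads, 3))
    out_T = np.empty(n_samples)
    out_E = np.empty(n_samples)
    out_K = np.empty(n_samples)
    if config.thermostat == "vrescale" and not math.isinf(config.tau_T):
        c_exp = math.exp(-config.dt / config.tau_T)
        r1_arr = rng.standard_normal(config.n_steps)
        s_arr = (
            rng.chisquare(nf - 1, config.n_steps)
            if nf > 1
            else np.zeros(config.n_steps)
        )
    else:
        c_exp = -1.0  # sentinel: no thermostat
        r1_arr = np.zeros(1)
        s_arr = np.zeros(1)
    bad_step = _kernels.fluid_nvt_loop(
        system.positions, system.velocities, system.masses, system.box,
        pi, pj, table.x0, table.dx, table.U, table.F,
        config.dt, config.n_steps, config.sample_interval, nf,
        0.5 * nf * KB * config.T_ref, c_exp,
        r1_arr, s_arr, out_pos, out_T, out_E, out_K, KB,
    )
    if bad_step >= 0:
        raise IntegrationBlowup(f"non-finite energy at step {bad_step}")
    frames = [
        CGFrame(out_pos[k], system.masses.copy(), list(system.bead_types),
                system.box.copy())
        for k in range(n_samples)
    ]
    times = config.dt * config.sample_interval * np.arange(1, n_samples + 1)
    return SimResult(frames, times, out_T, out_E, out_K, system)


def run_nvt(
    system: CGSystem,
    config: SimulationConfig,
    callbacks: Sequence[Callable[[int, CGSystem], None]] | None = None,
) -> SimResult:
    """Integrate n_steps of NVT dynamics, sampling every sample_interval.

    The system is advanced in place (pass ``system.copy()`` to keep the
    input).  All randomness comes from ``config.seed``, so a repeated
    run is bit-identical.
    """
    cache = _PairCache(system)
    if callbacks is None and _fused_loop_applicable(system, config):
        return _run_nvt_fused(system, config, cache)
    rng = np.random.default_rng(config.seed)
    frames: list[CGFrame] = []
    times, temps, pots, kins = [], [], [], []
    for step in range(config.n_steps):
        forces, energy = compute_forces(system, cache)
        leapfrog_step(system, config, forces, step)
        remove_com_motion(system)
        if config.thermostat == "vrescale":
            vrescale_thermostat(system, config, rng)
        elif config.thermostat == "berendsen":
            berendsen_thermostat(system, config)
        if (step + 1) % config.sample_interval == 0:
            frames.append(system.as_frame())
            times.append((step + 1) * config.dt)
            temps.append(
                instantaneous_temperature(system) if system.mobile.any() else 0.0
            )
            pots.append(energy)
            kins.append(kinetic_energy(system))
        if callbacks:
            for cb in callbacks:
                cb(step, system)
    return SimResult(
        frames, np.array(times), np.array(temps), np.array(pots),
        np.array(kins), system,
    )
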