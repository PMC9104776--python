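"""The Iterative Boltzmann Inversion refinement loop.

Starting from the potential of mean force of a target RDF, each
iteration runs CG-MD under the current table, measures the resulting
g_n(r), and corrects the non-bonded potential with

    U_{n+1}(r) = U_n(r) + kB T ln( g_n(r) / g_target(r) ) + dU(r)

where dU(r) = alpha (1 - r/r_cut) is a small linear tail correction
(alpha = -0.001 kB T by default).  Convergence is scored by the
weighted least-squares functional

    f_target = integral  e^{-r} ( g(r) - g_target(r) )^2 dr

with r in nm.  Iteration stops when f_target drops below the tolerance
or the iteration cap is reached; the best-scoring iteration is
reported, not necessarily the last.

By Henderson's uniqueness theorem the pair potential reproducing a
given g(r) at a state point is unique up to a constant, so the fixed
point of this map is the potential that makes the CG model reproduce
the target structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .distributions import TabulatedFunction, radial_distribution, smooth_table
from .inversion import G_FLOOR, PotentialTable, apply_cutoff, central_difference_force
from .simulate import CGSystem, SimulationConfig, initialize_velocities, pair_key, run_nvt
from .units import thermal_energy

logger = logging.getLogger(__name__)

#: Cap (in units of kB T) on the per-iteration update in bins where one
#: of the distributions is unsampled, preventing runaway walls.
UNSAMPLED_CAP_KT = 2.0


@dataclass
class IBIConfig:
    """Settings of the iteration engine.

    ``alpha_coeff`` multiplies kB T to give the tail-correction
    amplitude; ``damping`` scales the ln-ratio increment (the fixed
    point is unchanged, only the path to it); ``iterate_pair`` names
    the single non-bonded type pair being refined.
    """

    max_iters: int = 100
    f_tol: float = 1e-4
    alpha_coeff: float = -0.001
    delta_u_enabled: bool = True
    r_cut: float = 1.0
    damping: float = 0.2
    smoothing_method: str | None = "savgol"
    smoothing_window: int = 5
    equilibration_fraction: float = 0.2
    iterate_pair: tuple[str, str] = ("AA", "AA")
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.f_tol <= 0:
            raise ValueError("f_tol must be positive")
        if not (0 < self.damping <= 1):
            raise ValueError("damping must be in (0, 1]")
        if not (0 <= self.equilibration_fraction < 1):
            raise ValueError("equilibration_fraction must be in [0, 1)")
        self.iterate_pair = pair_key(*self.iterate_pair)


@dataclass
class IterationRecord:
    """Archive entry for one scored iteration."""

    n: int
    f: float
    seed: int
    U: PotentialTable
    g: TabulatedFunction


@dataclass
class IBIState:
    """State of the loop at a reported (best) iteration."""

    n: int
    U_n: PotentialTable
    g_n: TabulatedFunction
    f_history: list[float]
    seed: int


def tail_correction_value(
    r: np.ndarray | float, alpha: float, r_cut: float
) -> np.ndarray | float:
    """dU(r) = alpha (1 - r/r_cut) inside the cutoff, zero beyond.

    dU(r_cut) = 0 and dU(0) = alpha exactly.
    """
    r = np.asarray(r, dtype=float)
    out = np.where(r <= r_cut, alpha * (1.0 - r / r_cut), 0.0)
    return out if out.ndim else float(out)


def linear_correction(
    x0: float, dx: float, n: int, alpha: float, r_cut: float
) -> TabulatedFunction:
    """Tabulate the linear tail correction on a uniform grid."""
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    x = x0 + dx * np.arange(n)
    return TabulatedFunction(x0, dx, tail_correction_value(x, alpha, r_cut), "potential")


def convergence_metric(g: TabulatedFunction, g_target: TabulatedFunction) -> float:
    """Weighted squared RDF mismatch, integral of e^{-r} (g - g_t)^2 dr."""
    if not g.same_grid(g_target):
        raise ValueError("g and g_target must share one grid")
    w = np.exp(-g.x)
    return float(np.trapezoid(w * (g.values - g_target.values) ** 2, dx=g.dx))


def ibi_update(
    U_n: PotentialTable,
    g_n: TabulatedFunction,
    g_target: TabulatedFunction,
    T: float,
    config: IBIConfig,
) -> PotentialTable:
    """One potential update U_{n+1} = U_n + kB T ln(g_n/g_target) + dU.

    The ln-ratio increment is evaluated where both distributions are
    sampled, capped at +/- 2 kB T where only one of them is, damped,
    and smoothed; a zero increment therefore reproduces U_n exactly
    (the fixed point).  The result is re-shifted to U(r_cut) = 0 and
    its force column rebuilt.
    """
    if not g_n.same_grid(g_target):
        raise ValueError("g_n and g_target grids differ")
    if g_n.n != U_n.n or abs(g_n.x0 - U_n.x0) > 1e-9 or abs(g_n.dx - U_n.dx) > 1e-9:
        raise ValueError("distribution grid does not match the potential grid")
    kT = thermal_energy(T)
    cap = UNSAMPLED_CAP_KT * kT
    gn, gt = g_n.values, g_target.values
    both = (gn > G_FLOOR) & (gt > G_FLOOR)
    only_t = (gn <= G_FLOOR) & (gt > G_FLOOR)
    only_n = (gn > G_FLOOR) & (gt <= G_FLOOR)
    incr = np.zeros_like(U_n.U)
    incr[both] = kT * np.log(gn[both] / gt[both])
    incr[only_t] = -cap   # CG misses structure the target has: deepen
    incr[only_n] = +cap   # CG over-structures an empty target bin: repel
    incr = np.clip(incr, -cap, cap) * config.damping
    if config.smoothing_method:
        incr_t = TabulatedFunction(U_n.x0, U_n.dx, incr, "potential")
        incr = smooth_table(
            incr_t, config.smoothing_method, config.smoothing_window
        ).values
    U_new = U_n.U + incr
    if config.delta_u_enabled:
        alpha = config.alpha_coeff * kT
        U_new = U_new + tail_correction_value(U_n.x, alpha, config.r_cut)
    if U_n.r_cut is not None:
        U_new = apply_cutoff(U_n.x, U_new, U_n.r_cut, U_n.dx)
    F_new = central_difference_force(U_n.x0, U_n.dx, U_new)
    if U_n.r_cut is not None:
        F_new[U_n.x >= U_n.r_cut - 1e-12] = 0.0
    return PotentialTable(
        U_n.x0, U_n.dx, U_new, F_new, r_core=U_n.r_core, r_cut=U_n.r_cut
    )


def measure_iteration_rdf(
    result_frames,
    g_target: TabulatedFunction,
    pair: tuple[str, str],
    exclusions: set[tuple[int, int]],
) -> TabulatedFunction:
    """Measure g_n on exactly the target grid with the frozen estimator."""
    r_max = g_target.x0 + g_target.dx * g_target.n - g_target.dx / 2.0
    return radial_distribution(
        result_frames, pair[0], pair[1], r_max=r_max, dx=g_target.dx,
        exclusions=exclusions,
    )


def run_ibi(
    initial_U: PotentialTable,
    g_target: TabulatedFunction,
    system_template: CGSystem,
    config: IBIConfig,
    archive_dir: str | Path | None = None,
) -> tuple[IBIState, list[IterationRecord]]:
    """Iterate CG-MD and potential updates until f_target <= f_tol.

    Each iteration n uses seed base_seed + n (recorded for replay),
    reinitializes velocities, carries positions forward, discards the
    equilibration fraction of sampled frames, and scores the remainder.
    Returns the best-f iteration state and the full archive.
    """
    from . import io as _io  # deferred: io depends on this module's types

    system = system_template.copy()
    pair = config.iterate_pair
    U = initial_U.copy()
    records: list[IterationRecord] = []
    f_history: list[float] = []
    best: IterationRecord | None = None

    if archive_dir is not None:
        archive_dir = Path(archive_dir)
        archive_dir.mkdir(parents=True, exist_ok=True)

    for n in range(config.max_iters + 1):
        seed_n = config.sim.seed + n
        system.nonbonded[pair] = U
        sim_cfg = SimulationConfig(
            dt=config.sim.dt, n_steps=config.sim.n_steps, T_ref=config.sim.T_ref,
            thermostat=config.sim.thermostat, tau_T=config.sim.tau_T,
            r_cut=config.sim.r_cut, seed=seed_n,
            sample_interval=config.sim.sample_interval,
        )
        initialize_velocities(
            system, sim_cfg.T_ref, np.random.default_rng(seed_n + 10_000_019)
        )
        result = run_nvt(system, sim_cfg)
        n_skip = int(len(result.frames) * config.equilibration_fraction)
        production = result.frames[n_skip:]
        g_n = measure_iteration_rdf(production, g_target, pair, system.exclusions)
        f = convergence_metric(g_n, g_target)
        record = IterationRecord(n=n, f=f, seed=seed_n, U=U.copy(), g=g_n)
        records.append(record)
        f_history.append(f)
        logger.info(
            "iteration %3d  f_target=%.6e  <T>=%.1f K  seed=%d",
            n, f, float(result.temperature.mean()), seed_n,
        )
        if archive_dir is not None:
            _io.write_iteration(archive_dir, record)
        if best is None or f < best.f:
            best = record
        if f <= config.f_tol or n == config.max_iters:
            break
        U = ibi_update(U, g_n, g_target, config.sim.T_ref, config)

    if archive_dir is not None:
        _io.write_archive_manifest(archive_dir, records, best.n, config)

    state = IBIState(
        n=best.n, U_n=best.U, g_n=best.g, f_history=f_history, seed=best.seed
    )
    return state, records
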