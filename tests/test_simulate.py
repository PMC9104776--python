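"""CG-MD engine: forces, leapfrog, thermostats, NVT runs."""

import math

import numpy as np
import pytest
import scipy.stats

from ibicg.inversion import PotentialTable
from ibicg.simulate import (
    CGSystem,
    ConfigurationError,
    IntegrationBlowup,
    SimulationConfig,
    berendsen_thermostat,
    compute_forces,
    initialize_velocities,
    instantaneous_temperature,
    kinetic_energy,
    leapfrog_step,
    run_nvt,
    vrescale_thermostat,
)
from ibicg.synthetic import harmonic_table, tabulate_12_6
from ibicg.units import KB
from conftest import make_fluid


def two_bead_system(r, table, box_l=4.0, types=("AA", "AA"), masses=(50.0, 50.0)):
    return CGSystem(
        positions=np.array([[1.0, 1.0, 1.0], [1.0 + r, 1.0, 1.0]]),
        velocities=np.zeros((2, 3)),
        masses=np.array(masses),
        bead_types=list(types),
        box=np.array([box_l] * 3),
        nonbonded={tuple(sorted(types)): table},
    )


class TestComputeForces:
    def test_zero_beyond_cutoff(self, lj_table):
        system = two_bead_system(1.5, lj_table)
        forces, energy = compute_forces(system)
        assert np.allclose(forces, 0.0)
        assert energy == 0.0

    def test_newtons_third_law_exact(self, rng, lj_table):
        system = make_fluid(30, 2.6, lj_table, rng)
        forces, _ = compute_forces(system)
        assert np.all(np.abs(forces.sum(axis=0)) < 1e-10)

    def test_pair_force_matches_table(self, lj_table):
        r = 0.5
        system = two_bead_system(r, lj_table)
        forces, energy = compute_forces(system)
        f_expected = lj_table.force(r)
        # force on bead 1 points along -x (toward/away from bead 0)
        assert forces[1, 0] == pytest.approx(f_expected, rel=1e-12)
        assert forces[0, 0] == pytest.approx(-f_expected, rel=1e-12)
        assert energy == pytest.approx(lj_table.energy(r), rel=1e-12)

    def test_numpy_and_kernel_paths_agree(self, rng, lj_table, monkeypatch):
        """The accelerated pair kernel must reproduce the reference
        numpy force loop to float accumulation accuracy."""
        import ibicg.simulate as sim

        system = make_fluid(40, 2.8, lj_table, rng)
        bond = harmonic_table(1000.0, 0.4, 0.2, 0.6, 0.001)
        system.bonds.append((0, 1, bond))
        system.exclusions.add((0, 1))
        f_active, e_active = compute_forces(system)
        monkeypatch.setattr(sim, "USE_NUMBA", False)
        f_ref, e_ref = compute_forces(system)
        assert np.allclose(f_active, f_ref, atol=1e-9)
        assert e_active == pytest.approx(e_ref, rel=1e-12)

    def test_unassigned_type_pair_rejected(self, lj_table):
        system = two_bead_system(0.5, lj_table)
        system.bead_types = ["AA", "XX"]
        with pytest.raises(ConfigurationError):
            compute_forces(system)

    def test_angle_force_matches_numerical_gradient(self):
        """Analytic bending forces against a central difference of the
        tabulated energy, displacing every coordinate in turn."""
        table = harmonic_table(0.5, 120.0, 60.0, 180.0, 0.01)  # fine theta grid
        pos = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 0.0], [-0.3, 0.8, 0.1]])
        system = CGSystem(
            positions=pos.copy(),
            velocities=np.zeros((3, 3)),
            masses=np.full(3, 50.0),
            bead_types=["A", "B", "C"],
            box=np.array([10.0] * 3),
            angles=[(0, 1, 2, table)],
            nonbonded={
                ("A", "B"): None, ("B", "C"): None, ("A", "C"): None,
            },
        )
        forces, _ = compute_forces(system)
        h = 1e-3
        for bead in range(3):
            for axis in range(3):
                for sign, store in ((1, "up"), (-1, "down")):
                    system.positions = pos.copy()
                    system.positions[bead, axis] += sign * h
                    _, e = compute_forces(system)
                    if store == "up":
                        e_up = e
                    else:
                        e_dn = e
                numeric = -(e_up - e_dn) / (2 * h)
                assert forces[bead, axis] == pytest.approx(
                    numeric, rel=1e-4, abs=1e-6
                )

    def test_bond_force_direction_restoring(self):
        bond = harmonic_table(1000.0, 0.4, 0.2, 0.6, 0.001)
        system = CGSystem(
            positions=np.array([[1.0, 1, 1], [1.5, 1, 1]]),  # stretched by 0.1
            velocities=np.zeros((2, 3)),
            masses=np.array([50.0, 50.0]),
            bead_types=["A", "A"],
            box=np.array([4.0] * 3),
            bonds=[(0, 1, bond)],
            nonbonded={("A", "A"): None},
        )
        forces, _ = compute_forces(system)
        assert forces[0, 0] > 0 and forces[1, 0] < 0  # pulled together


class TestLeapfrog:
    def test_free_flight_is_exact(self):
        system = two_bead_system(1.5, tabulate_12_6(0.0, 0.47))
        system.velocities[:] = [[0.1, 0.05, -0.02], [0.1, 0.05, -0.02]]
        v0 = system.velocities.copy()
        x0 = system.positions.copy()
        cfg = SimulationConfig(dt=0.002, n_steps=1, thermostat="none")
        for step in range(100):
            forces, _ = compute_forces(system)
            leapfrog_step(system, cfg, forces, step)
        assert np.allclose(system.velocities, v0)
        expected = (x0 + 100 * cfg.dt * v0) % 4.0
        assert np.allclose(system.positions, expected, atol=1e-12)

    def test_harmonic_bond_period(self):
        """Oscillation period of a tabulated harmonic bond matches
        2 pi sqrt(mu/k) within 1% at dt = period/100."""
        k, l0, m = 1000.0, 0.4, 50.0
        mu = m / 2
        period = 2 * math.pi * math.sqrt(mu / k)
        bond = harmonic_table(k, l0, 0.25, 0.55, 0.0002)
        system = CGSystem(
            positions=np.array([[1.0, 1, 1], [1.0 + l0 + 0.05, 1, 1]]),
            velocities=np.zeros((2, 3)),
            masses=np.array([m, m]),
            bead_types=["A", "A"],
            box=np.array([4.0] * 3),
            bonds=[(0, 1, bond)],
            nonbonded={("A", "A"): None},
        )
        cfg = SimulationConfig(dt=period / 100, n_steps=520, thermostat="none",
                               sample_interval=1)
        result = run_nvt(system, cfg)
        lengths = np.array(
            [f.positions[1, 0] - f.positions[0, 0] for f in result.frames]
        )
        ext = lengths - l0
        crossings = np.flatnonzero(np.diff(np.sign(ext)) != 0)
        # linear interpolation of crossing times; full period = 2 crossings
        t = result.times
        tc = [
            t[i] + (t[i + 1] - t[i]) * ext[i] / (ext[i] - ext[i + 1])
            for i in crossings
        ]
        measured = 2 * np.mean(np.diff(tc))
        assert measured == pytest.approx(period, rel=0.01)

    def test_nve_energy_conservation(self, rng, lj_table):
        """Total energy drift below 1e-3 of the kinetic scale over 1e4
        steps at a conservative timestep."""
        system = make_fluid(64, 3.2, lj_table, rng)
        initialize_velocities(system, 330.0, rng)
        cfg = SimulationConfig(dt=0.0005, n_steps=10_000, thermostat="none",
                               sample_interval=10, seed=3)
        result = run_nvt(system, cfg)
        e_tot = result.potential + result.kinetic
        scale = result.kinetic.mean()
        assert np.ptp(e_tot) / scale < 1e-3

    def test_blowup_reported_with_step(self, lj_table):
        """Non-finite coordinates abort integration, naming the step."""
        system = two_bead_system(0.5, lj_table)
        bad_forces = np.full((2, 3), np.nan)
        with pytest.raises(IntegrationBlowup, match="step 17"):
            leapfrog_step(system, SimulationConfig(dt=0.001), bad_forces, step=17)


class TestTemperature:
    def test_zero_velocities_zero_kelvin(self, small_fluid):
        assert instantaneous_temperature(small_fluid) == 0.0

    def test_maxwell_boltzmann_sample_reads_back(self, lj_table):
        rng = np.random.default_rng(42)
        n = 10_000
        system = CGSystem(
            positions=rng.uniform(0, 10, (n, 3)),
            velocities=np.zeros((n, 3)),
            masses=np.full(n, 57.0),
            bead_types=["AA"] * n,
            box=np.array([10.0] * 3),
            nonbonded={("AA", "AA"): None},
        )
        system.velocities = rng.standard_normal((n, 3)) * math.sqrt(KB * 330 / 57.0)
        assert instantaneous_temperature(system) == pytest.approx(330, abs=5)

    def test_doubling_speeds_quadruples_T(self, small_fluid, rng):
        initialize_velocities(small_fluid, 200.0, rng)
        T1 = instantaneous_temperature(small_fluid)
        small_fluid.velocities *= 2
        assert instantaneous_temperature(small_fluid) == pytest.approx(4 * T1, rel=1e-12)

    def test_initialize_velocities_exact_setpoint(self, small_fluid, rng):
        initialize_velocities(small_fluid, 273.0, rng)
        assert instantaneous_temperature(small_fluid) == pytest.approx(273.0, rel=1e-12)


def ideal_gas_system(n, rng, mass=57.0):
    return CGSystem(
        positions=rng.uniform(0, 5, (n, 3)),
        velocities=np.zeros((n, 3)),
        masses=np.full(n, mass),
        bead_types=["AA"] * n,
        box=np.array([5.0] * 3),
        nonbonded={("AA", "AA"): None},
    )


class TestThermostats:
    def test_vrescale_infinite_tau_is_identity(self, rng):
        system = ideal_gas_system(50, rng)
        initialize_velocities(system, 300.0, rng)
        v0 = system.velocities.copy()
        cfg = SimulationConfig(T_ref=300.0, tau_T=np.inf)
        vrescale_thermostat(system, cfg, np.random.default_rng(0))
        assert np.array_equal(system.velocities, v0)

    def test_vrescale_canonical_mean_and_variance(self, rng):
        """Long-run kinetic energy must match the canonical ensemble:
        <K> = (Nf/2) kB T within 1%, Var(K) = (Nf/2) (kB T)^2 within 5%."""
        system = ideal_gas_system(100, rng)
        initialize_velocities(system, 330.0, rng)
        nf = 3 * 100 - 3
        cfg = SimulationConfig(dt=0.001, n_steps=100_000, T_ref=330.0,
                               tau_T=0.02, seed=9, sample_interval=5)
        result = run_nvt(system, cfg)
        K = result.kinetic[2000:]
        kt = KB * 330.0
        assert K.mean() == pytest.approx(0.5 * nf * kt, rel=0.01)
        assert K.var() == pytest.approx(0.5 * nf * kt**2, rel=0.05)

    def test_speed_distribution_is_maxwellian(self, rng, lj_table):
        """KS test of sampled speeds against the Maxwell distribution.
        Uses an interacting fluid: collisions are what mix velocity
        directions (a global rescale alone cannot)."""
        system = make_fluid(64, 2.6, lj_table, rng)
        initialize_velocities(system, 330.0, rng)
        # discard initial relaxation from the lattice start
        run_nvt(system, SimulationConfig(dt=0.001, n_steps=3000, T_ref=330.0,
                                         seed=20, sample_interval=3000))
        speeds = []
        for seg in range(157):
            cfg = SimulationConfig(dt=0.001, n_steps=300, T_ref=330.0,
                                   tau_T=0.1, seed=21 + seg, sample_interval=300)
            run_nvt(system, cfg)
            speeds.append(np.linalg.norm(system.velocities, axis=1))
        speeds = np.concatenate(speeds)
        scale = math.sqrt(KB * 330.0 / 57.052)
        stat = scipy.stats.kstest(speeds, "maxwell", args=(0, scale))
        assert len(speeds) >= 10_000
        assert stat.pvalue > 0.01

    def test_berendsen_scaling_formula(self, rng):
        system = ideal_gas_system(40, rng)
        initialize_velocities(system, 250.0, rng)
        v0 = system.velocities.copy()
        cfg = SimulationConfig(dt=0.002, T_ref=330.0, tau_T=0.1,
                               thermostat="berendsen")
        T = instantaneous_temperature(system)
        lam = math.sqrt(1 + (0.002 / 0.1) * (330.0 / T - 1))
        berendsen_thermostat(system, cfg)
        assert np.allclose(system.velocities, lam * v0, rtol=1e-12)

    def test_berendsen_at_setpoint_is_identity(self, rng):
        system = ideal_gas_system(40, rng)
        initialize_velocities(system, 330.0, rng)
        v0 = system.velocities.copy()
        berendsen_thermostat(
            system, SimulationConfig(T_ref=330.0, tau_T=0.1, thermostat="berendsen")
        )
        assert np.allclose(system.velocities, v0, rtol=1e-12)

    def test_berendsen_cold_start_warms_monotonically(self, rng, lj_table):
        system = make_fluid(27, 2.5, lj_table, rng)
        initialize_velocities(system, 100.0, rng)
        cfg = SimulationConfig(dt=0.001, T_ref=330.0, tau_T=0.05,
                               thermostat="berendsen")
        temps = []
        for _ in range(30):
            berendsen_thermostat(system, cfg)
            temps.append(instantaneous_temperature(system))
        assert all(b > a for a, b in zip(temps, temps[1:]))
        assert temps[-1] < 330.0


class TestRunNvt:
    def test_frozen_system_frames_identical(self, small_fluid):
        small_fluid.frozen[:] = True
        result = run_nvt(small_fluid, SimulationConfig(n_steps=50, sample_interval=10,
                                                       thermostat="none"))
        for frame in result.frames[1:]:
            assert np.array_equal(frame.positions, result.frames[0].positions)

    def test_frozen_beads_feel_force_but_never_move(self, lj_table):
        system = two_bead_system(0.45, lj_table)
        system.frozen = np.array([True, False])
        forces, _ = compute_forces(system)
        assert abs(forces[0, 0]) > 0
        x_frozen = system.positions[0].copy()
        run_nvt(system, SimulationConfig(n_steps=200, thermostat="none",
                                         sample_interval=50))
        assert np.array_equal(system.positions[0], x_frozen)

    def test_mean_temperature_tracks_setpoint(self, rng, lj_table):
        system = make_fluid(64, 2.6, lj_table, rng)
        initialize_velocities(system, 330.0, rng)
        cfg = SimulationConfig(dt=0.001, n_steps=20_000, T_ref=330.0,
                               seed=4, sample_interval=10)
        result = run_nvt(system, cfg)
        mean_T = result.temperature[len(result.temperature) // 2:].mean()
        assert mean_T == pytest.approx(330.0, rel=0.02)

    @pytest.mark.parametrize("preset", ["fluid", "bonded"])
    def test_same_seed_reproduces_run_bitwise(self, rng, lj_table, preset):
        def build():
            if preset == "fluid":
                return make_fluid(27, 2.5, lj_table, np.random.default_rng(5))
            bond = harmonic_table(1000.0, 0.4, 0.2, 0.6, 0.001)
            sys_ = make_fluid(8, 2.5, lj_table, np.random.default_rng(5))
            sys_.bonds.append((0, 1, bond))
            return CGSystem(
                sys_.positions, sys_.velocities, sys_.masses, sys_.bead_types,
                sys_.box, [(0, 1, bond)], [], dict(sys_.nonbonded),
            )

        results = []
        for _ in range(2):
            system = build()
            initialize_velocities(system, 330.0, np.random.default_rng(17))
            cfg = SimulationConfig(dt=0.001, n_steps=500, T_ref=330.0,
                                   seed=8, sample_interval=50)
            results.append(run_nvt(system, cfg))
        a, b = results
        assert np.array_equal(a.temperature, b.temperature)
        assert np.array_equal(a.frames[-1].positions, b.frames[-1].positions)

    def test_mobile_momentum_removed(self, rng, lj_table):
        system = make_fluid(27, 2.5, lj_table, rng)
        initialize_velocities(system, 330.0, rng)
        run_nvt(system, SimulationConfig(n_steps=500, seed=2, sample_interval=100))
        p = system.masses @ system.velocities
        assert np.all(np.abs(p) < 1e-9)

    def test_rdf_robust_to_timestep(self, lj_table):
        """g(r) from dt=1 fs and dt=2 fs runs of the same fluid agree
        within sampling noise."""
        from ibicg.distributions import radial_distribution

        gs = []
        for dt, steps in ((0.001, 30_000), (0.002, 15_000)):
            system = make_fluid(64, 2.6, lj_table, np.random.default_rng(6))
            initialize_velocities(system, 330.0, np.random.default_rng(7))
            cfg = SimulationConfig(dt=dt, n_steps=steps, T_ref=330.0, seed=10,
                                   sample_interval=10)
            result = run_nvt(system, cfg)
            skip = len(result.frames) // 5
            gs.append(
                radial_distribution(result.frames[skip:], "AA", "AA",
                                    r_max=1.0, dx=0.02)
            )
        diff = np.abs(gs[0].values - gs[1].values)
        r = gs[0].x
        assert diff[r > 0.35].max() < 0.15
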