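"""Self-contained reference structures and closure fixtures.

The reference all-atom ensembles behind a real coarse-graining study
are long solvated trajectories that cannot ship with a toolkit.  This
module therefore generates everything the pipeline needs from code:

* armchair carbon-nanotube coordinates commensurate with a periodic
  box (rolled-graphene construction),
* schematic capped-amino-acid structures with composition-correct
  group masses (acetyl cap / residue / amine cap), and
* *closure fixtures*: CG systems with a known ground-truth potential
  whose target distributions are produced by this package's own MD
  engine.  Inverting those targets and iterating must recover the
  ground truth — a self-consistency test that exercises the whole
  pipeline without any external data.

Every fixture is regenerable from (seed, parameters) alone; the
provenance record stored on the fixture is sufficient for bit-exact
replay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .distributions import (
    TabulatedFunction,
    angle_distribution,
    bond_distribution,
    radial_distribution,
)
from .inversion import PotentialTable, apply_cutoff, central_difference_force
from .mapping import AtomFrame, MappingScheme, apply_mapping, build_peptide_mapping
from .simulate import CGSystem, SimulationConfig, initialize_velocities, pair_key, run_nvt
from .units import KB

CARBON_MASS = 12.011

ELEMENT_MASSES = {
    "C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06,
}

#: Residue-unit formulas (amino acid minus water) for the 20 standard
#: amino acids, as (C, H, N, O, S) counts.
RESIDUE_FORMULAS: dict[str, tuple[int, int, int, int, int]] = {
    "GLY": (2, 3, 1, 1, 0),
    "ALA": (3, 5, 1, 1, 0),
    "SER": (3, 5, 1, 2, 0),
    "PRO": (5, 7, 1, 1, 0),
    "VAL": (5, 9, 1, 1, 0),
    "THR": (4, 7, 1, 2, 0),
    "CYS": (3, 5, 1, 1, 1),
    "LEU": (6, 11, 1, 1, 0),
    "ILE": (6, 11, 1, 1, 0),
    "ASN": (4, 6, 2, 2, 0),
    "ASP": (4, 5, 1, 3, 0),
    "GLN": (5, 8, 2, 2, 0),
    "LYS": (6, 12, 2, 1, 0),
    "GLU": (5, 7, 1, 3, 0),
    "MET": (5, 9, 1, 1, 1),
    "HIS": (6, 7, 3, 1, 0),
    "PHE": (9, 9, 1, 1, 0),
    "ARG": (6, 12, 4, 1, 0),
    "TYR": (9, 9, 1, 2, 0),
    "TRP": (11, 10, 2, 1, 0),
}

ACE_FORMULA = (2, 3, 0, 1, 0)   # acetyl cap CH3-CO-
NH2_FORMULA = (0, 2, 1, 0, 0)   # amine cap -NH2

_ELEMENTS = ("C", "H", "N", "O", "S")


def formula_mass(formula: tuple[int, int, int, int, int]) -> float:
    """Mass in amu of a (C, H, N, O, S) composition."""
    return sum(n * ELEMENT_MASSES[e] for n, e in zip(formula, _ELEMENTS))


def residue_mass(residue_name: str) -> float:
    """Residue-unit mass in amu (e.g. GLY -> 57.05)."""
    key = residue_name.upper()
    if key not in RESIDUE_FORMULAS:
        raise ValueError(f"unknown residue {residue_name!r}")
    return formula_mass(RESIDUE_FORMULAS[key])


def generate_cnt_coordinates(
    chirality: tuple[int, int] = (5, 5),
    box_length_z: float = 2.93,
    cc_bond: float = 0.142,
    box_xy: float = 4.16,
) -> AtomFrame:
    """Armchair (n,n) nanotube spanning a periodic box along z.

    Rolled-graphene construction: radius R = 3 n a_cc / (2 pi), axial
    period sqrt(3) a_cc with two rings of 2n atoms per period.  The
    box length must be an integer number of periods to within 15% of
    one period; the tube is then strained axially (at most a percent
    or two) to close exactly across the boundary, which is what makes
    the tube effectively infinite.  Atoms are ordered ring by ring in
    ascending z, so consecutive groups of atoms are axial slices.
    """
    n, m = chirality
    if n != m:
        raise ValueError("only armchair (n,n) tubes are supported")
    period = math.sqrt(3.0) * cc_bond
    n_cells_f = box_length_z / period
    n_cells = round(n_cells_f)
    if n_cells < 1 or abs(n_cells_f - n_cells) > 0.15:
        raise ValueError(
            f"box_length_z={box_length_z} nm is not commensurate with the "
            f"tube period {period:.4f} nm ({n_cells_f:.3f} cells)"
        )
    period_eff = box_length_z / n_cells
    radius = 3.0 * n * cc_bond / (2.0 * math.pi)
    # half-angle of the in-ring bonded pair
    w = 2.0 * math.asin(cc_bond / (2.0 * radius))
    cx = cy = box_xy / 2.0
    positions = []
    for cell in range(n_cells):
        for ring in range(2):
            z = (cell + 0.5 * ring) * period_eff
            offset = 0.0 if ring == 0 else math.pi / n
            for k in range(n):
                base = 2.0 * math.pi * k / n + offset
                for sign in (-0.5, 0.5):
                    phi = base + sign * w
                    positions.append(
                        (cx + radius * math.cos(phi),
                         cy + radius * math.sin(phi),
                         z)
                    )
    positions = np.array(positions)
    n_atoms = len(positions)
    return AtomFrame(
        positions=positions,
        masses=np.full(n_atoms, CARBON_MASS),
        labels=["C"] * n_atoms,
        box=np.array([box_xy, box_xy, box_length_z]),
    )


def generate_capped_residue(
    residue_name: str,
    center: np.ndarray | None = None,
    box: tuple[float, float, float] = (4.16, 4.16, 2.93),
    seed: int = 0,
) -> tuple[AtomFrame, MappingScheme]:
    """Schematic capped amino acid: three atom clusters (ACE, residue,
    NH2) with composition-correct masses, plus its three-bead mapping.

    The geometry is deliberately coarse (clusters of element-mass
    atoms around three sites 0.35 nm apart); only masses and topology
    are meant to be realistic, since the CG targets in this package
    come from the CG engine itself.
    """
    key = residue_name.upper()
    if key not in RESIDUE_FORMULAS:
        raise ValueError(f"unknown residue {residue_name!r}")
    box = np.asarray(box, dtype=float)
    if center is None:
        center = box / 2.0
    rng = np.random.default_rng(seed)
    groups = [
        ("ACE", ACE_FORMULA, center + np.array([-0.35, 0.0, 0.0])),
        ("AA", RESIDUE_FORMULAS[key], center),
        ("NH2", NH2_FORMULA, center + np.array([0.35, 0.0, 0.0])),
    ]
    positions, masses, labels = [], [], []
    group_indices: list[np.ndarray] = []
    idx = 0
    for _, formula, site in groups:
        members = []
        for count, element in zip(formula, _ELEMENTS):
            for _ in range(count):
                positions.append(site + 0.06 * rng.standard_normal(3))
                masses.append(ELEMENT_MASSES[element])
                labels.append(element)
                members.append(idx)
                idx += 1
        group_indices.append(np.array(members))
    frame = AtomFrame(np.array(positions), np.array(masses), labels, box)
    scheme = build_peptide_mapping(group_indices[0], group_indices[1], group_indices[2])
    return frame, scheme


def tabulate_12_6(
    epsilon: float,
    sigma: float,
    r_cut: float = 1.0,
    r_min: float | None = None,
    dx: float = 0.002,
) -> PotentialTable:
    """Tabulated truncated-shifted 12-6 potential.

    U(r) = 4 eps ((sigma/r)^12 - (sigma/r)^6) - U(r_cut) inside the
    cutoff, zero beyond.  The force column is built by the same
    central-difference rule the rest of the toolkit uses, so tabulated
    force and energy are mutually consistent under interpolation.
    """
    if epsilon < 0 or sigma <= 0:
        raise ValueError("need epsilon >= 0 and sigma > 0")
    if r_min is None:
        r_min = 0.65 * sigma
    n = int(round((r_cut - r_min) / dx)) + 1
    x = r_min + dx * np.arange(n)
    sr6 = (sigma / x) ** 6
    U = 4.0 * epsilon * (sr6**2 - sr6)
    U = apply_cutoff(x, U, r_cut, dx)
    F = central_difference_force(r_min, dx, U)
    F[x >= r_cut - 1e-12] = 0.0
    return PotentialTable(r_min, dx, U, F, r_core=r_min, r_cut=r_cut)


def harmonic_table(
    k: float,
    x_eq: float,
    x0: float,
    x_max: float,
    dx: float,
) -> PotentialTable:
    """Tabulated harmonic potential U = k/2 (x - x_eq)^2, no cutoff.

    Used for ground-truth bond tables (x in nm, k in kJ/(mol nm^2))
    and angle tables (x in degrees, k in kJ/(mol deg^2)).
    """
    n = int(round((x_max - x0) / dx)) + 1
    x = x0 + dx * np.arange(n)
    U = 0.5 * k * (x - x_eq) ** 2
    F = central_difference_force(x0, dx, U)
    return PotentialTable(x0, dx, U, F, r_core=x0, r_cut=None)


@dataclass
class DistributionSet:
    """Target distributions of one reference ensemble."""

    rdf: TabulatedFunction
    bond: dict[str, TabulatedFunction] = field(default_factory=dict)
    angle: dict[str, TabulatedFunction] = field(default_factory=dict)


@dataclass
class ClosureFixture:
    """A CG system, its ground-truth potential, and the target
    distributions that potential generates under this engine."""

    ground_truth: PotentialTable
    system: CGSystem
    target_dists: DistributionSet
    provenance: dict

    def provenance_kwargs(self) -> dict:
        """Arguments that regenerate this fixture via make_closure_fixture."""
        return dict(self.provenance)


def build_fluid_system(
    n_mobile: int, box_l: float, truth: PotentialTable | None, mass: float,
    rng: np.random.Generator,
) -> CGSystem:
    """Jittered-lattice single-component fluid of 'AA' beads."""
    n_side = math.ceil(n_mobile ** (1.0 / 3.0))
    spacing = box_l / n_side
    sites = np.array(
        [(i, j, k) for i in range(n_side) for j in range(n_side) for k in range(n_side)],
        dtype=float,
    )[:n_mobile]
    positions = (sites + 0.5) * spacing + 0.05 * spacing * rng.standard_normal(
        (n_mobile, 3)
    )
    return CGSystem(
        positions=positions,
        velocities=np.zeros((n_mobile, 3)),
        masses=np.full(n_mobile, mass),
        bead_types=["AA"] * n_mobile,
        box=np.array([box_l, box_l, box_l]),
        nonbonded={("AA", "AA"): truth},
    )


def build_cnt_peptide_system(
    residue_name: str = "TRP",
    box: tuple[float, float, float] = (4.16, 4.16, 2.93),
    atoms_per_bead: int = 10,
    cnt_bond_k: float = 50_000.0,
    cnt_angle_k_deg: float = 0.30,
    peptide_bond_k: float = 4_000.0,
    seed: int = 0,
) -> CGSystem:
    """CG system of the study geometry: a periodically bonded nanotube
    bead chain plus one mobile three-bead capped amino acid.

    The tube beads are mobile and held together by harmonic-table
    bonds and near-straight angle terms, with bonds closing across the
    z boundary; tube-tube non-bonded interactions are explicitly off.
    The peptide starts about 1 nm from the tube axis.
    """
    from .mapping import build_cnt_mapping

    box = np.asarray(box, dtype=float)
    tube = generate_cnt_coordinates(box_length_z=float(box[2]), box_xy=float(box[0]))
    order = np.argsort(tube.positions[:, 2], kind="stable")
    scheme = build_cnt_mapping(tube.n_atoms, atoms_per_bead, order)
    cnt_cg = apply_mapping(tube, scheme)
    n_cnt = cnt_cg.n_beads
    spacing = float(box[2]) / n_cnt

    pep_frame, pep_scheme = generate_capped_residue(residue_name, seed=seed, box=tuple(box))
    pep_cg = apply_mapping(pep_frame, pep_scheme)
    # place the peptide chain ~1 nm off the tube axis
    axis = np.array([box[0] / 2.0, box[1] / 2.0, box[2] / 2.0])
    shift = axis + np.array([1.0, 0.0, 0.0]) - pep_cg.positions[1]
    pep_pos = pep_cg.positions + shift

    positions = np.vstack([cnt_cg.positions, pep_pos])
    masses = np.concatenate([cnt_cg.masses, pep_cg.masses])
    types = list(cnt_cg.bead_types) + list(pep_cg.bead_types)

    cnt_bond = harmonic_table(cnt_bond_k, spacing, max(0.02, spacing - 0.08),
                              spacing + 0.08, 0.001)
    cnt_angle = harmonic_table(cnt_angle_k_deg, 180.0, 90.0, 180.0, 0.5)
    pep_bond = harmonic_table(peptide_bond_k, 0.35, 0.15, 0.65, 0.002)
    pep_angle = harmonic_table(0.02, 160.0, 60.0, 180.0, 0.5)

    bonds = [(i, (i + 1) % n_cnt, cnt_bond) for i in range(n_cnt)]
    angles = [(i, (i + 1) % n_cnt, (i + 2) % n_cnt, cnt_angle) for i in range(n_cnt)]
    i_ace, i_aa, i_nh2 = n_cnt, n_cnt + 1, n_cnt + 2
    bonds += [(i_ace, i_aa, pep_bond), (i_aa, i_nh2, pep_bond)]
    angles += [(i_ace, i_aa, i_nh2, pep_angle)]

    nonbonded: dict[tuple[str, str], PotentialTable | None] = {
        pair_key("AA", "CNT"): tabulate_12_6(2.0, 0.55),
        pair_key("ACE", "CNT"): tabulate_12_6(1.0, 0.50),
        pair_key("NH2", "CNT"): tabulate_12_6(1.0, 0.45),
        pair_key("CNT", "CNT"): None,
        pair_key("AA", "ACE"): None,
        pair_key("AA", "NH2"): None,
        pair_key("ACE", "NH2"): None,
    }
    return CGSystem(
        positions=positions,
        velocities=np.zeros((len(masses), 3)),
        masses=masses,
        bead_types=types,
        box=box.copy(),
        bonds=bonds,
        angles=angles,
        nonbonded=nonbonded,
    )


def make_closure_fixture(
    kind: str = "fluid",
    epsilon: float = 1.5,
    sigma: float = 0.47,
    n_mobile: int = 300,
    box: float = 4.3,
    T: float = 330.0,
    seed: int = 7,
    steps: int = 300_000,
    dt: float = 0.001,
    sample_interval: int = 10,
    dx: float = 0.01,
    r_cut: float = 1.0,
    equilibration_fraction: float = 0.2,
    residue_name: str = "TRP",
) -> ClosureFixture:
    """Generate a closure fixture: run NVT under a known potential and
    record the distributions it produces as the matching targets.

    ``fluid`` builds a single-component bead fluid (the workhorse for
    iteration closure tests: many equivalent pairs give a low-noise
    RDF); ``cnt-peptide`` builds the nanotube-plus-capped-residue
    geometry of the study system.  The target run is sampled after
    discarding the equilibration fraction.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    rng = np.random.default_rng(seed)
    truth = tabulate_12_6(epsilon, sigma, r_cut=r_cut)

    if kind == "fluid":
        if r_cut > box / 2.0:
            raise ValueError("box too small for the requested cutoff")
        system = build_fluid_system(n_mobile, box, truth, residue_mass("GLY"), rng)
        pair = ("AA", "AA")
        boxv = system.box
    elif kind == "cnt-peptide":
        system = build_cnt_peptide_system(residue_name=residue_name, seed=seed)
        system.nonbonded[pair_key("AA", "CNT")] = truth
        pair = pair_key("AA", "CNT")
        boxv = system.box
        if r_cut > boxv.min() / 2.0:
            raise ValueError("box too small for the requested cutoff")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    cfg = SimulationConfig(
        dt=dt, n_steps=steps, T_ref=T, thermostat="vrescale",
        tau_T=0.1, r_cut=r_cut, seed=seed, sample_interval=sample_interval,
    )
    initialize_velocities(system, T, np.random.default_rng(seed + 10_000_019))
    work = system.copy()
    result = run_nvt(work, cfg)
    n_skip = int(len(result.frames) * equilibration_fraction)
    production = result.frames[n_skip:]

    r_max = r_cut
    rdf = radial_distribution(
        production, pair[0], pair[1], r_max=r_max, dx=dx,
        exclusions=system.exclusions,
    )
    dists = DistributionSet(rdf=rdf)
    if kind == "cnt-peptide":
        n_cnt = sum(1 for t in system.bead_types if t == "CNT")
        cnt_bonds = [(i, (i + 1) % n_cnt) for i in range(n_cnt)]
        pep_bonds = [(n_cnt, n_cnt + 1), (n_cnt + 1, n_cnt + 2)]
        dists.bond["CNT-CNT"] = bond_distribution(production, cnt_bonds, l_max=0.3)
        dists.bond["peptide"] = bond_distribution(production, pep_bonds, l_max=0.8)
        cnt_angles = [(i, (i + 1) % n_cnt, (i + 2) % n_cnt) for i in range(n_cnt)]
        dists.angle["CNT-CNT-CNT"] = angle_distribution(production, cnt_angles)
        dists.angle["peptide"] = angle_distribution(
            production, [(n_cnt, n_cnt + 1, n_cnt + 2)]
        )

    provenance = {
        "kind": kind, "epsilon": epsilon, "sigma": sigma,
        "n_mobile": n_mobile, "box": box, "T": T, "seed": seed,
        "steps": steps, "dt": dt, "sample_interval": sample_interval,
        "dx": dx, "r_cut": r_cut,
        "equilibration_fraction": equilibration_fraction,
        "residue_name": residue_name,
    }
    return ClosureFixture(
        ground_truth=truth, system=system, target_dists=dists,
        provenance=provenance,
    )


def make_noisy_target(
    fixture: ClosureFixture, noise_sd: float, seed: int = 0
) -> DistributionSet:
    """Perturb the fixture's targets with zero-mean Gaussian noise.

    The RDF is clipped at zero; bond and angle distributions are
    clipped and renormalized.  Models the sampling noise a finite
    reference trajectory would carry.
    """
    rng = np.random.default_rng(seed)
    src = fixture.target_dists

    def perturb(t: TabulatedFunction, renorm: bool) -> TabulatedFunction:
        vals = np.clip(t.values + noise_sd * rng.standard_normal(t.n), 0.0, None)
        out = TabulatedFunction(t.x0, t.dx, vals, t.kind)
        return out.normalized() if renorm and noise_sd > 0 else out

    return DistributionSet(
        rdf=perturb(src.rdf, renorm=False),
        bond={k: perturb(v, renorm=True) for k, v in src.bond.items()},
        angle={k: perturb(v, renorm=True) for k, v in src.angle.items()},
    )
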