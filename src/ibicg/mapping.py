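"""Center-of-mass mapping from all-atom frames to coarse-grained beads.

A mapping scheme partitions (a subset of) the atom indices of a frame
into typed bead groups; each bead inherits the summed mass of its
members and sits at their center of mass.  Two concrete schemes are
provided: the carbon-nanotube scheme (consecutive axial groups of a
fixed number of carbons per bead) and the capped-amino-acid scheme
(acetyl cap, residue, amine cap -> three beads).

Groups that straddle a periodic boundary are made whole before the COM
is taken: every member atom is shifted by the minimum image relative to
the group's first atom, so the COM of e.g. a nanotube ring crossing the
box edge lands on the ring and not in the middle of the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pbc import minimum_image


@dataclass
class AtomFrame:
    """One all-atom configuration.

    positions : (N, 3) nm; masses : (N,) amu; labels : length-N atom
    names; box : (3,) orthorhombic edge lengths in nm; velocities :
    optional (N, 3) nm/ps.
    """

    positions: np.ndarray
    masses: np.ndarray
    labels: list[str]
    box: np.ndarray
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.positions)
        if not (len(self.masses) == len(self.labels) == n):
            raise ValueError(
                f"inconsistent frame: {n} positions, {len(self.masses)} masses, "
                f"{len(self.labels)} labels"
            )
        if np.any(self.masses <= 0):
            raise ValueError("all atom masses must be positive")
        if np.any(self.box <= 0):
            raise ValueError("all box edges must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


@dataclass
class MappingScheme:
    """Partition of atom indices into typed beads.

    beads is an ordered list of (bead_type, atom_indices); indices must
    be pairwise disjoint across beads.  solvent_indices are atoms
    excluded from mapping altogether (the CG model is implicit-solvent).
    """

    beads: list[tuple[str, np.ndarray]]
    solvent_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.beads = [(t, np.asarray(ix, dtype=int)) for t, ix in self.beads]
        self.solvent_indices = np.asarray(self.solvent_indices, dtype=int)
        seen: set[int] = set()
        for t, ix in self.beads:
            if len(ix) == 0:
                raise ValueError(f"bead of type {t!r} has no atoms")
            overlap = seen.intersection(ix.tolist())
            if overlap:
                raise ValueError(f"atom indices shared between beads: {sorted(overlap)}")
            seen.update(ix.tolist())

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def bead_types(self) -> list[str]:
        return [t for t, _ in self.beads]

    def validate_against(self, frame: AtomFrame) -> None:
        for t, ix in self.beads:
            if ix.min() < 0 or ix.max() >= frame.n_atoms:
                raise ValueError(
                    f"bead {t!r} references atom index outside frame of "
                    f"{frame.n_atoms} atoms"
                )


@dataclass
class CGFrame:
    """One coarse-grained configuration (bead positions in nm)."""

    positions: np.ndarray
    masses: np.ndarray
    bead_types: list[str]
    box: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.box = np.asarray(self.box, dtype=float)

    @property
    def n_beads(self) -> int:
        return len(self.positions)


def center_of_mass(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position, R = sum(m_i r_i) / sum(m_i).

    Inputs are not unwrapped here; callers dealing with periodic
    systems must make the group whole first (see apply_mapping).
    """
    positions = np.asarray(positions, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if positions.size == 0:
        raise ValueError("cannot take the center of mass of an empty group")
    if len(positions) != len(masses):
        raise ValueError("positions and masses differ in length")
    if np.any(masses <= 0):
        raise ValueError("all masses must be positive")
    return masses @ positions / masses.sum()


def apply_mapping(frame: AtomFrame, scheme: MappingScheme) -> CGFrame:
    """Map an all-atom frame onto CG beads by center of mass.

    Each bead group is made whole across the periodic boundary
    (minimum image relative to its first atom) before the COM is
    computed; the total mapped mass is conserved exactly.
    """
    scheme.validate_against(frame)
    pos = np.empty((scheme.n_beads, 3))
    mass = np.empty(scheme.n_beads)
    for b, (_, ix) in enumerate(scheme.beads):
        group = frame.positions[ix]
        ref = group[0]
        whole = ref + minimum_image(group - ref, frame.box)
        pos[b] = center_of_mass(whole, frame.masses[ix])
        mass[b] = frame.masses[ix].sum()
    return CGFrame(pos, mass, scheme.bead_types, frame.box.copy())


def build_cnt_mapping(
    n_atoms: int,
    atoms_per_bead: int,
    axis_sorted_indices: np.ndarray | None = None,
) -> MappingScheme:
    """Group nanotube carbons into beads of ``atoms_per_bead`` atoms each.

    Atoms are grouped consecutively along the tube axis (pass the atom
    indices sorted by axial coordinate); each group of e.g. 10 carbons
    becomes one ``CNT`` bead, so a 240-atom tube yields 24 beads.  The
    atom count must divide exactly.
    """
    if atoms_per_bead <= 0:
        raise ValueError("atoms_per_bead must be positive")
    if n_atoms % atoms_per_bead != 0:
        raise ValueError(
            f"{n_atoms} atoms do not divide into beads of {atoms_per_bead}"
        )
    if axis_sorted_indices is None:
        axis_sorted_indices = np.arange(n_atoms)
    axis_sorted_indices = np.asarray(axis_sorted_indices, dtype=int)
    if len(axis_sorted_indices) != n_atoms:
        raise ValueError("axis_sorted_indices must cover every atom exactly once")
    beads = [
        ("CNT", axis_sorted_indices[i : i + atoms_per_bead])
        for i in range(0, n_atoms, atoms_per_bead)
    ]
    return MappingScheme(beads)


def build_peptide_mapping(
    ace_indices: np.ndarray,
    residue_indices: np.ndarray,
    nh2_indices: np.ndarray,
) -> MappingScheme:
    """Three-bead scheme for a capped amino acid: ACE cap, residue, NH2 cap.

    The whole residue (main chain plus side chain) collapses onto a
    single ``AA`` bead; each terminal blocking group gets its own bead.
    Bead order is always (ACE, AA, NH2) along the chain.
    """
    groups = [
        ("ACE", np.asarray(ace_indices, dtype=int)),
        ("AA", np.asarray(residue_indices, dtype=int)),
        ("NH2", np.asarray(nh2_indices, dtype=int)),
    ]
    for name, ix in groups:
        if len(ix) == 0:
            raise ValueError(f"{name} group is empty")
    return MappingScheme(groups)


def map_trajectory(frames: list[AtomFrame], scheme: MappingScheme) -> list[CGFrame]:
    """Apply one mapping scheme to every frame of a trajectory."""
    return [apply_mapping(f, scheme) for f in frames]
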