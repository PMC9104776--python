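"""Shared fixtures: small deterministic systems built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from ibicg.mapping import AtomFrame, CGFrame
from ibicg.simulate import CGSystem
from ibicg.synthetic import tabulate_12_6


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def lj_table():
    """Moderate 12-6 table used as a generic non-bonded interaction."""
    return tabulate_12_6(epsilon=1.5, sigma=0.47, r_cut=1.0)


def make_fluid(n: int, box_l: float, table, rng: np.random.Generator,
               bead_type: str = "AA", mass: float = 57.052) -> CGSystem:
    """Random non-overlapping fluid of one bead type (jittered lattice)."""
    n_side = int(np.ceil(n ** (1 / 3)))
    sites = np.array(
        [(i, j, k) for i in range(n_side) for j in range(n_side) for k in range(n_side)],
        dtype=float,
    )[:n]
    spacing = box_l / n_side
    pos = (sites + 0.5) * spacing + 0.05 * spacing * rng.standard_normal((n, 3))
    return CGSystem(
        positions=pos,
        velocities=np.zeros((n, 3)),
        masses=np.full(n, mass),
        bead_types=[bead_type] * n,
        box=np.array([box_l] * 3),
        nonbonded={(bead_type, bead_type): table},
    )


@pytest.fixture()
def small_fluid(rng, lj_table):
    return make_fluid(27, 2.5, lj_table, rng)


def random_cg_frames(
    rng: np.random.Generator, n_beads: int, n_frames: int, box_l: float,
    types: list[str] | None = None,
) -> list[CGFrame]:
    """Uniform random bead positions — an ideal gas of frames."""
    types = types or ["AA"] * n_beads
    box = np.array([box_l] * 3)
    return [
        CGFrame(rng.uniform(0, box_l, (n_beads, 3)), np.ones(n_beads), types, box)
        for _ in range(n_frames)
    ]


@pytest.fixture()
def tiny_atom_frame():
    """Four atoms, two bead groups, in a small box."""
    return AtomFrame(
        positions=np.array(
            [[0.5, 0.5, 0.5], [0.7, 0.5, 0.5], [1.5, 1.5, 1.5], [1.5, 1.7, 1.5]]
        ),
        masses=np.array([12.0, 12.0, 14.0, 16.0]),
        labels=["C", "C", "N", "O"],
        box=np.array([3.0, 3.0, 3.0]),
    )
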