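"""Readers and writers for every on-disk artifact.

GRO structures go through MDAnalysis (positions at GRO's fixed
3-decimal nm precision, velocities preserved when present).  Tables —
distributions and potentials — are whitespace-delimited text with
``#``-prefixed ``key = value`` header lines carrying kind, grid and
provenance; potential files are plain 3-column (r, U, -U') text under
the header, the GROMACS tabulated-potential layout.  Trajectories use
a plain-text multi-frame dialect so no test or pipeline step ever
needs a binary file.  The iteration archive is a directory of
``iter_NNN/`` subdirectories plus a JSON manifest and a CSV f-history
from which a run can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
import yaml

from .distributions import TabulatedFunction
from .inversion import PotentialTable
from .mapping import AtomFrame, CGFrame
from .synthetic import ELEMENT_MASSES

if TYPE_CHECKING:  # pragma: no cover
    from .ibi import IBIConfig, IterationRecord


class HeaderError(ValueError):
    """A table file is missing a required header key."""


def _fmt(value) -> str:
    """Shortest exact decimal representation of a float."""
    return repr(float(value))


# ---------------------------------------------------------------- GRO

def write_gro(path: str | Path, frame: AtomFrame | CGFrame, title: str = "ibicg") -> None:
    """Write a structure as GRO; bead/atom labels become residue and
    atom names, one residue per particle."""
    import MDAnalysis as mda

    labels = frame.labels if isinstance(frame, AtomFrame) else frame.bead_types
    n = len(frame.positions)
    has_vel = isinstance(frame, AtomFrame) and frame.velocities is not None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=n, atom_resindex=np.arange(n),
            residue_segindex=np.zeros(n, dtype=int),
            trajectory=True, velocities=has_vel,
        )
        u.add_TopologyAttr("names", labels)
        u.add_TopologyAttr("resnames", [lab[:5] for lab in labels])
        u.add_TopologyAttr("resids", np.arange(1, n + 1))
        u.dimensions = [*(np.asarray(frame.box) * 10.0), 90.0, 90.0, 90.0]
        u.atoms.positions = np.asarray(frame.positions) * 10.0
        if has_vel:
            u.atoms.velocities = np.asarray(frame.velocities) * 10.0
        u.atoms.write(str(path))


def read_gro(path: str | Path, masses: np.ndarray | None = None) -> AtomFrame:
    """Read a GRO structure into an AtomFrame (nm, nm/ps).

    GRO carries no masses; pass them explicitly, or the first letter
    of each atom name is treated as an element symbol (C, H, N, O, S).
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), to_guess=())
        ts = u.trajectory.ts
        positions = u.atoms.positions / 10.0
        box = u.dimensions[:3] / 10.0
        labels = [str(nm) for nm in u.atoms.names]
        velocities = u.atoms.velocities / 10.0 if ts.has_velocities else None
    if masses is None:
        try:
            masses = np.array([ELEMENT_MASSES[lab[0].upper()] for lab in labels])
        except KeyError as exc:
            raise ValueError(
                f"cannot infer a mass for atom name {exc}; pass masses explicitly"
            ) from None
    return AtomFrame(positions, np.asarray(masses, dtype=float), labels,
                     box, velocities)


# -------------------------------------------------------------- tables

def _write_header(fh, meta: dict) -> None:
    for key, value in meta.items():
        fh.write(f"# {key} = {value}\n")


def _read_header(path: Path) -> tuple[dict, np.ndarray]:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            rows.append([float(tok) for tok in line.split()])
    return meta, np.array(rows)


def write_table(
    path: str | Path,
    table: TabulatedFunction | PotentialTable,
    provenance: dict | None = None,
) -> None:
    """Write a table with a self-describing header.

    Distributions are two columns (x, value); potentials are three
    columns (r, U, -U') so the data block doubles as a GROMACS-style
    tabulated potential.
    """
    path = Path(path)
    meta: dict = {}
    if isinstance(table, PotentialTable):
        meta.update(kind="potential", x0=_fmt(table.x0), dx=_fmt(table.dx),
                    n=table.n, r_core=_fmt(table.r_core),
                    r_cut="none" if table.r_cut is None else _fmt(table.r_cut),
                    columns="r U -U'")
    else:
        meta.update(kind=table.kind, x0=_fmt(table.x0), dx=_fmt(table.dx),
                    n=table.n, columns="x value")
    meta["units"] = "nm, kJ/mol (angles in degrees)"
    if provenance:
        reserved = set(meta)
        for k, v in provenance.items():
            key = str(k)
            # provenance must not shadow the grid/kind contract keys
            meta[f"src_{key}" if key in reserved else key] = v
    with open(path, "w") as fh:
        _write_header(fh, meta)
        if isinstance(table, PotentialTable):
            for x, u, f in zip(table.x, table.U, table.F):
                fh.write(f"{_fmt(x)} {_fmt(u)} {_fmt(f)}\n")
        else:
            for x, v in zip(table.x, table.values):
                fh.write(f"{_fmt(x)} {_fmt(v)}\n")


def read_table(path: str | Path) -> TabulatedFunction | PotentialTable:
    """Read a table written by write_table; exact round trip."""
    path = Path(path)
    meta, data = _read_header(path)
    for key in ("kind", "x0", "dx", "n"):
        if key not in meta:
            raise HeaderError(f"{path}: missing required header key {key!r}")
    kind = meta["kind"]
    x0, dx = float(meta["x0"]), float(meta["dx"])
    if kind == "potential":
        if data.shape[1] != 3:
            raise HeaderError(f"{path}: potential tables need 3 columns")
        r_cut = None if meta.get("r_cut", "none") == "none" else float(meta["r_cut"])
        return PotentialTable(
            x0, dx, data[:, 1], data[:, 2],
            r_core=float(meta.get("r_core", x0)), r_cut=r_cut,
        )
    return TabulatedFunction(x0, dx, data[:, 1], kind)


# ---------------------------------------------------------- trajectory

def write_trajectory(path: str | Path, frames: Sequence[CGFrame],
                     times: np.ndarray | None = None) -> None:
    """Plain-text multi-frame trajectory (nm, ps)."""
    if not frames:
        raise ValueError("no frames to write")
    first = frames[0]
    with open(path, "w") as fh:
        fh.write(f"# ibicg trajectory nbeads = {first.n_beads}\n")
        fh.write("# types = " + " ".join(first.bead_types) + "\n")
        fh.write("# masses = " + " ".join(_fmt(m) for m in first.masses) + "\n")
        for i, frame in enumerate(frames):
            t = 0.0 if times is None else float(times[i])
            fh.write(f"FRAME {i} {_fmt(t)}\n")
            fh.write("BOX " + " ".join(_fmt(b) for b in frame.box) + "\n")
            for p in frame.positions:
                fh.write(f"{_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}\n")


def read_trajectory(path: str | Path) -> tuple[list[CGFrame], np.ndarray]:
    """Read a trajectory written by write_trajectory."""
    types: list[str] = []
    masses = np.array([])
    frames: list[CGFrame] = []
    times: list[float] = []
    box = None
    rows: list[list[float]] = []

    def flush() -> None:
        if rows:
            frames.append(CGFrame(np.array(rows), masses, types, box))
            rows.clear()

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("# types ="):
                types = line.split("=", 1)[1].split()
            elif line.startswith("# masses ="):
                masses = np.array([float(t) for t in line.split("=", 1)[1].split()])
            elif line.startswith("#"):
                continue
            elif line.startswith("FRAME"):
                flush()
                times.append(float(line.split()[2]))
            elif line.startswith("BOX"):
                box = np.array([float(t) for t in line.split()[1:]])
            else:
                rows.append([float(t) for t in line.split()])
    flush()
    return frames, np.array(times)


# -------------------------------------------------------------- config

def _from_mapping(cls, data: dict, context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {context} key(s): {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path):
    """Load a YAML run configuration.

    Top-level sections ``simulation`` and ``ibi`` mirror the
    SimulationConfig and IBIConfig fields one to one; an empty file
    yields all defaults; unknown keys are rejected by name.
    """
    from .ibi import IBIConfig
    from .simulate import SimulationConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration file must be a mapping")
    unknown = set(raw) - {"simulation", "ibi"}
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    sim = _from_mapping(SimulationConfig, raw.get("simulation") or {}, "simulation")
    ibi_data = dict(raw.get("ibi") or {})
    if "iterate_pair" in ibi_data:
        ibi_data["iterate_pair"] = tuple(ibi_data["iterate_pair"])
    ibi = _from_mapping(IBIConfig, {**ibi_data, "sim": sim}, "ibi")
    return sim, ibi


def config_snapshot(config) -> dict:
    """JSON-serializable snapshot of a (possibly nested) config."""
    return dataclasses.asdict(config)


# ------------------------------------------------------------- archive

def write_iteration(archive_dir: str | Path, record: "IterationRecord") -> None:
    """Write one iteration's potential, RDF and summary line."""
    it_dir = Path(archive_dir) / f"iter_{record.n:03d}"
    it_dir.mkdir(parents=True, exist_ok=True)
    write_table(it_dir / "potential.dat", record.U,
                provenance={"iteration": record.n, "seed": record.seed})
    write_table(it_dir / "rdf.dat", record.g,
                provenance={"iteration": record.n, "seed": record.seed})
    (it_dir / "summary.txt").write_text(
        f"n = {record.n}\nf_target = {record.f!r}\nseed = {record.seed}\n"
    )


def write_archive_manifest(
    archive_dir: str | Path,
    records: Sequence["IterationRecord"],
    best_iteration: int,
    config: "IBIConfig",
) -> None:
    """Write manifest.json and f_history.csv for a finished run."""
    archive_dir = Path(archive_dir)
    entries = [
        {
            "n": r.n, "f_target": r.f, "seed": r.seed,
            "potential": f"iter_{r.n:03d}/potential.dat",
            "rdf": f"iter_{r.n:03d}/rdf.dat",
        }
        for r in records
    ]
    manifest = {
        "format": "ibicg-archive-1",
        "best_iteration": int(best_iteration),
        "iterations": entries,
        "config": config_snapshot(config),
    }
    (archive_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    pd.DataFrame(
        {"n": [r.n for r in records], "f_target": [r.f for r in records],
         "seed": [r.seed for r in records]}
    ).to_csv(archive_dir / "f_history.csv", index=False)


def read_archive_manifest(archive_dir: str | Path) -> dict:
    """Load and validate a run manifest; referenced files must exist
    and best_iteration must attain the minimum f_target."""
    archive_dir = Path(archive_dir)
    manifest = json.loads((archive_dir / "manifest.json").read_text())
    for entry in manifest["iterations"]:
        for key in ("potential", "rdf"):
            if not (archive_dir / entry[key]).exists():
                raise FileNotFoundError(f"archive refers to missing {entry[key]}")
    fs = [e["f_target"] for e in manifest["iterations"]]
    best = manifest["best_iteration"]
    best_f = next(e["f_target"] for e in manifest["iterations"] if e["n"] == best)
    if best_f > min(fs) + 1e-300:
        raise ValueError("manifest best_iteration does not attain the minimum f")
    return manifest
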