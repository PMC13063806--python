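"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats: multi-frame GRO (fixed-width, nm, box on the last line of
each frame), XYZ (Angstrom, converted to nm on read), the per-atom topology
TSV, surface-pressure/area isotherm CSV, and result tables as TSV.  Only
rectangular boxes are accepted; triclinic GRO box lines are rejected.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError
from .isotherm import Isotherm
from .trajectory import TOPOLOGY_COLUMNS, Frame, Topology, Trajectory

_ANGSTROM_PER_NM = 10.0


def read_trajectory(path, fmt: str = "gro") -> tuple[Trajectory, list[str]]:
    """Read a multi-frame GRO or XYZ file.

    Returns the trajectory (nm) and the per-atom names of the first frame.
    GRO coordinates are taken as nm; XYZ as Angstrom and converted.
    """
    if fmt == "gro":
        return _read_gro(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown trajectory format {fmt!r}; use 'gro' or 'xyz'")


def _read_gro(path) -> tuple[Trajectory, list[str]]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    frames: list[Frame] = []
    names: list[str] = []
    i = 0
    first_n = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        m = re.search(r"t=\s*([-\d.eE+]+)", title)
        time = float(m.group(1)) if m else float(len(frames))
        try:
            n = int(lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: bad atom-count line after '{title}'") from exc
        if first_n is None:
            first_n = n
        elif n != first_n:
            raise FormatError(
                f"{path}: atom count changed between frames ({first_n} -> {n})"
            )
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n or i + 2 + n >= len(lines) + 1:
            raise FormatError(f"{path}: truncated frame")
        coords = np.empty((n, 3))
        frame_names = []
        for j, ln in enumerate(body):
            try:
                frame_names.append(ln[10:15].strip())
                coords[j] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: malformed atom line: {ln!r}") from exc
        try:
            box_fields = [float(x) for x in lines[i + 2 + n].split()]
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: missing or malformed box line") from exc
        if len(box_fields) not in (3, 9):
            raise FormatError(f"{path}: box line must have 3 or 9 fields")
        if len(box_fields) == 9 and any(abs(v) > 1e-9 for v in box_fields[3:]):
            raise FormatError(
                f"{path}: triclinic boxes are not supported (rectangular cells only)"
            )
        frames.append(Frame(coords, np.array(box_fields[:3]), time))
        if not names:
            names = frame_names
        i += 2 + n + 1
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return Trajectory.from_frames(frames), names


def write_gro(path, traj: Trajectory, topology: Topology | None = None) -> None:
    """Write a trajectory as multi-frame GRO (coordinates to 3 decimals, nm)."""
    if topology is not None and topology.n_atoms != traj.n_atoms:
        raise SchemaError("topology size does not match trajectory")
    with open(path, "w") as fh:
        for f in traj:
            fh.write(f"memraft frame t= {f.time:.4f}\n{f.n_atoms}\n")
            for j in range(f.n_atoms):
                if topology is not None:
                    row = topology.table.iloc[j]
                    resid = int(row["residue_id"]) % 100000
                    resname = str(row["species"])[:5]
                    name = str(row["atom_name"])[:5]
                    atomid = int(row["atom_id"]) % 100000
                else:
                    resid, resname, name, atomid = 1, "UNK", "X", (j + 1) % 100000
                x, y, z = f.coordinates[j]
                fh.write(
                    f"{resid:5d}{resname:<5s}{name:>5s}{atomid:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{f.box[0]:10.5f}{f.box[1]:10.5f}{f.box[2]:10.5f}\n")


def _read_xyz(path) -> tuple[Trajectory, list[str]]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    frames = []
    names: list[str] = []
    i = 0
    first_n = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"{path}: expected atom count, got {lines[i]!r}") from exc
        if first_n is None:
            first_n = n
        elif n != first_n:
            raise FormatError(f"{path}: atom count changed between frames")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = re.search(r"box=\s*([-\d.eE+]+)[ ,]+([-\d.eE+]+)[ ,]+([-\d.eE+]+)", comment)
        # XYZ has no mandatory cell; default to a generous cube when absent
        box = (
            np.array([float(m.group(k)) for k in (1, 2, 3)]) / _ANGSTROM_PER_NM
            if m
            else np.full(3, 1000.0)
        )
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise FormatError(f"{path}: truncated XYZ frame")
        coords = np.empty((n, 3))
        frame_names = []
        for j, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: malformed XYZ atom line: {ln!r}")
            frame_names.append(parts[0])
            coords[j] = [float(p) for p in parts[1:4]]
        frames.append(Frame(coords / _ANGSTROM_PER_NM, box, float(len(frames))))
        if not names:
            names = frame_names
        i += 2 + n
    return Trajectory.from_frames(frames), names


def write_xyz(path, traj: Trajectory, names: list[str] | None = None) -> None:
    """Write a trajectory as XYZ (Angstrom)."""
    with open(path, "w") as fh:
        for f in traj:
            fh.write(f"{f.n_atoms}\n")
            bx = f.box * _ANGSTROM_PER_NM
            fh.write(f"box= {bx[0]:.4f} {bx[1]:.4f} {bx[2]:.4f}\n")
            for j in range(f.n_atoms):
                nm = names[j] if names else "X"
                x, y, z = f.coordinates[j] * _ANGSTROM_PER_NM
                fh.write(f"{nm:<4s} {x:12.5f} {y:12.5f} {z:12.5f}\n")


def read_topology(path) -> Topology:
    """Read a topology TSV with the canonical column schema."""
    p = Path(path)
    if p.stat().st_size == 0:
        raise SchemaError(f"{path}: empty topology file")
    df = pd.read_csv(p, sep="\t")
    if df.empty:
        raise SchemaError(f"{path}: topology table has no rows")
    missing = [c for c in TOPOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df["leaflet_hint"] = df["leaflet_hint"].fillna("")
    return Topology(df)


def write_topology(path, topology: Topology) -> None:
    topology.table.to_csv(path, sep="\t", index=False)


def read_isotherm_csv(path) -> list[Isotherm]:
    """Read isotherms from CSV, one :class:`Isotherm` per (mole_fraction, replicate).

    Required columns: ``area_A2``, ``pi_mN_m``, ``mole_fraction``, ``replicate``.
    """
    p = Path(path)
    if p.stat().st_size == 0:
        raise SchemaError(f"{path}: empty isotherm file")
    df = pd.read_csv(p)
    required = ["area_A2", "pi_mN_m", "mole_fraction", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: isotherm table has no rows")
    out = []
    for (frac, rep), grp in df.groupby(["mole_fraction", "replicate"], sort=True):
        out.append(
            Isotherm(
                area_A2=grp["area_A2"].to_numpy(float),
                pi_mN_m=grp["pi_mN_m"].to_numpy(float),
                mole_fraction=float(frac),
                replicate=rep,
            )
        )
    return out


def write_isotherm_csv(path, isotherms: list[Isotherm]) -> None:
    rows = []
    for iso in isotherms:
        for a, p_ in zip(iso.area_A2, iso.pi_mN_m):
            rows.append(
                {
                    "area_A2": a,
                    "pi_mN_m": p_,
                    "mole_fraction": iso.mole_fraction,
                    "replicate": iso.replicate,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_results(path, table: pd.DataFrame) -> None:
    """Write a results table as TSV (mean +/- sd column layout preserved)."""
    if table.empty:
        raise SchemaError("refusing to write an empty results table")
    table.to_csv(path, sep="\t", index=False)
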