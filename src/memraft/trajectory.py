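"""Core in-memory containers: frames, trajectories and per-atom topology.

Unit conventions used throughout the package: lengths in nm, times in ns,
masses in amu.  Lateral diffusion coefficients are reported in cm^2/s
(1 nm^2/ns = 1e-5 cm^2/s).  Boxes are rectangular; triclinic cells are
rejected at the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, TopologyError

#: Allowed subregion tags for lipid/ligand atoms.
SUBREGIONS = frozenset(
    {"choline", "phosphate", "glycerol", "tails", "sterol", "ligand", "other"}
)

#: Subregion tags counted as membrane "headgroup" in SASA partitioning and
#: density-region work (sterol hydroxyls sit at the headgroup level).
HEADGROUP_SUBREGIONS = frozenset({"choline", "phosphate", "glycerol", "sterol"})

#: Required columns of a topology table, in canonical order.
TOPOLOGY_COLUMNS = (
    "atom_id",
    "atom_name",
    "residue_id",
    "species",
    "subregion",
    "element",
    "mass_amu",
    "vdw_radius_nm",
    "is_donor",
    "is_hydrogen",
    "is_acceptor",
    "donor_of",
    "leaflet_hint",
)


@dataclass
class Frame:
    """A single configuration: coordinates (nm), rectangular box (nm), time (ns)."""

    coordinates: np.ndarray  # (N, 3)
    box: np.ndarray  # (3,)
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (N, 3)")
        if self.box.shape != (3,):
            raise ValueError("box must be a length-3 vector (rectangular cell)")
        if not np.all(self.box > 0):
            raise ValueError("box components must be positive")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    @property
    def area(self) -> float:
        """Projected xy box area in nm^2."""
        return float(self.box[0] * self.box[1])


@dataclass
class Trajectory:
    """Stacked multi-frame coordinates with per-frame boxes and times.

    ``coordinates`` has shape (n_frames, n_atoms, 3); ``boxes`` (n_frames, 3).
    """

    coordinates: np.ndarray
    boxes: np.ndarray
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must be (n_frames, n_atoms, 3)")
        if self.boxes.shape != (self.n_frames, 3):
            raise ValueError("boxes must be (n_frames, 3)")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.n_frames,):
            raise ValueError("times must be (n_frames,)")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def areas(self) -> np.ndarray:
        """Per-frame projected xy box area, nm^2."""
        return self.boxes[:, 0] * self.boxes[:, 1]

    def frame(self, i: int) -> Frame:
        return Frame(self.coordinates[i], self.boxes[i], float(self.times[i]))

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    @classmethod
    def from_frames(cls, frames) -> "Trajectory":
        frames = list(frames)
        if not frames:
            raise ValueError("cannot build a Trajectory from zero frames")
        coords = np.stack([f.coordinates for f in frames])
        boxes = np.stack([f.box for f in frames])
        times = np.array([f.time for f in frames])
        return cls(coords, boxes, times)


class Topology:
    """Per-atom annotation table with derived index sets.

    Wraps a DataFrame with columns :data:`TOPOLOGY_COLUMNS`.  ``donor_of``
    holds, for each hydrogen, the ``atom_id`` of its bonded donor heavy atom
    (-1 for non-hydrogens).  Row order is the atom order of the trajectory.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in TOPOLOGY_COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(f"topology table missing required columns: {missing}")
        table = table.reset_index(drop=True)
        bad = set(table["subregion"]) - SUBREGIONS
        if bad:
            raise SchemaError(
                f"unknown subregion labels {sorted(bad)}; "
                f"must be one of {sorted(SUBREGIONS)}"
            )
        if not (table["vdw_radius_nm"] > 0).all():
            raise SchemaError("vdw_radius_nm must be positive for every atom")
        for col in ("is_donor", "is_hydrogen", "is_acceptor"):
            table[col] = table[col].astype(bool)
        # every hydrogen must point at exactly one donor heavy atom
        hyd = table[table["is_hydrogen"]]
        ids = set(table["atom_id"])
        for _, row in hyd.iterrows():
            if row["donor_of"] not in ids:
                raise TopologyError(
                    f"hydrogen atom {row['atom_id']} has no bonded donor "
                    f"(donor_of={row['donor_of']})"
                )
        self.table = table
        self._id_to_index = pd.Series(table.index.values, index=table["atom_id"])

    @property
    def n_atoms(self) -> int:
        return len(self.table)

    def index_of(self, atom_ids) -> np.ndarray:
        """Positional indices for the given atom ids."""
        return self._id_to_index.loc[np.atleast_1d(atom_ids)].to_numpy()

    # ---- derived index sets (positional, into the coordinate array) ----

    def atoms_of_species(self, *species: str) -> np.ndarray:
        return np.flatnonzero(self.table["species"].isin(species).to_numpy())

    def atoms_of_subregion(self, *subregion: str) -> np.ndarray:
        return np.flatnonzero(self.table["subregion"].isin(subregion).to_numpy())

    def heavy_atoms(self, within: np.ndarray | None = None) -> np.ndarray:
        mask = ~self.table["is_hydrogen"].to_numpy()
        idx = np.flatnonzero(mask)
        if within is not None:
            idx = np.intersect1d(idx, within)
        return idx

    def hydrogens(self) -> np.ndarray:
        return np.flatnonzero(self.table["is_hydrogen"].to_numpy())

    def donors(self) -> np.ndarray:
        return np.flatnonzero(self.table["is_donor"].to_numpy())

    def acceptors(self) -> np.ndarray:
        return np.flatnonzero(self.table["is_acceptor"].to_numpy())

    def donor_index_of_hydrogen(self, h_index: int) -> int:
        """Positional index of the donor heavy atom bonded to hydrogen ``h_index``."""
        donor_id = self.table.iloc[h_index]["donor_of"]
        return int(self._id_to_index.loc[donor_id])

    def residues(self) -> pd.core.groupby.DataFrameGroupBy:
        return self.table.groupby("residue_id", sort=True)

    def reference_atoms(self) -> pd.DataFrame:
        """One headgroup reference atom per lipid residue.

        The reference is the phosphorus atom ("P") for phospholipid-like
        species and the hydroxyl oxygen ("O3") for sterols.  Ligand and
        untagged residues are skipped.  Raises :class:`TopologyError` if a
        lipid residue lacks its reference atom.
        """
        rows = []
        for rid, grp in self.residues():
            sub = set(grp["subregion"])
            if sub <= {"ligand", "other"}:
                continue
            ref = grp[grp["atom_name"].isin(("P", "O3"))]
            if len(ref) != 1:
                raise TopologyError(
                    f"lipid residue {rid} must have exactly one reference atom "
                    f"named 'P' or 'O3'; found {len(ref)}"
                )
            rows.append(ref.iloc[0])
        if not rows:
            raise TopologyError("no lipid residues with reference atoms found")
        refs = pd.DataFrame(rows).reset_index(drop=True)
        refs["atom_index"] = self.index_of(refs["atom_id"].to_numpy())
        return refs

    def __len__(self) -> int:
        return self.n_atoms


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return delta - box * np.round(delta / box)


def wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary cell [0, box)."""
    return np.mod(coords, box)
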